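# serpinkit

A toolkit for annotating plant serpins (serine-proteinase inhibitors) from
their reactive-centre loops (RCLs), with supporting comparative and
expression analyses:

- **RCL annotation** — locate the hinge anchor Glu (P17), lay out canonical
  P positions by counting C-terminal from it, extract the P2-P1′ triplet,
  classify serpins as inhibitory / non-inhibitory / uncertain, and scan
  the plant-specific `YxxGxDxRxF` motif.
- **Nomenclature** — reactive-centre-based names (`OsSRP-LRS` style) with a
  deterministic per-species collision rule, plus physico-chemical residue
  classes and P1 censuses.
- **Gene-model curation** — landmark-anchored edit scripts that transform
  database-predicted protein models into curated models with full residue
  accounting; the six rice revision recipes are packaged.
- **Identity matrices** — pairwise percent identity with pairwise gap
  exclusion, gap-column stripping, and display banding.
- **Phylogeny** — neighbor joining with a deterministic tie rule, site
  bootstrap supports counted on reference-tree bipartitions, Newick output.
- **qPCR quantification** — crossing-point (CP) transformation on the
  100,000-units-at-CP-20 scale, reference-gene normalisation, CP > 36
  detection calls, and in-silico amplicon prediction for primer tables.
- **Synthetic data** — seeded generators for serpin-like sequences with
  planted hinges/codes, families simulated down planted trees, and CP
  tables with known gene/reference ratios, so every operation is testable
  offline.

Packaged fixtures (under `src/serpinkit/data/`) hold the 14-locus rice
reactive-centre table, the two primer tables, the curation recipes and a
table of recorded (deliberately unreconciled) locus-assignment conflicts.

## CLI

A single entry point `serpinkit` multiplexes the subcommands:

```sh
serpinkit annotate --in proteins.fasta --out annotations.tsv [--config annot.toml]
serpinkit name --annotations annotations.tsv --out names.tsv
serpinkit curate --in raw.fasta --scripts rice_scripts.cfg --out curated.fasta --report report.tsv
serpinkit identity --aln curated.aln --out identity.tsv [--sites all|ungapped]
serpinkit tree --aln curated.aln --bootstrap 1000 --seed 42 --out tree.nwk
serpinkit qpcr --cp cps.tsv --reference Actin --out abundances.tsv
serpinkit amplicon --template gene.fasta --primers primers.tsv
serpinkit simulate serpin|family|qpcr [--spec spec.toml] --seed N --out ...
```

Every output file carries a header with the tool version, a configuration
hash and the seed; re-running with identical inputs reproduces outputs
byte-for-byte. Coordinates are 0-based half-open internally and 1-based
in all user-facing reports.

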