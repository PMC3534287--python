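"""Landmark-based curation of database-predicted serpin gene models.

Each revision is expressed as an :class:`EditScript`: an ordered list of
edits anchored on short unique substrings (landmarks) rather than absolute
coordinates, so that the edit remains auditable across annotation
releases.  Applying a script yields the curated sequence together with a
per-op residue accounting report; a declared expected final length that
does not match is a hard error, never a silent pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "EditError",
    "EditOp",
    "EditScript",
    "EditReport",
    "apply_edit_script",
    "build_rice_scripts",
    "parse_scripts_config",
    "format_scripts_config",
    "validate_intron_count",
    "EXPECTED_INTRONS",
]


class EditError(ValueError):
    """Raised when a landmark cannot be resolved or accounting fails."""


OP_KINDS = {
    "trim_n_terminal_to",
    "trim_n_terminal_count",
    "excise",
    "replace_c_terminal",
    "remove_run",
}


@dataclass(frozen=True)
class EditOp:
    kind: str
    landmark: Optional[str] = None        # trim_n_terminal_to
    count: Optional[int] = None           # trim_n_terminal_count / remove_run
    start_landmark: Optional[str] = None  # excise
    end_landmark: Optional[str] = None    # excise
    old_suffix: Optional[str] = None      # replace_c_terminal
    new_suffix: Optional[str] = None      # replace_c_terminal
    residue: Optional[str] = None         # remove_run

    def __post_init__(self) -> None:
        if self.kind not in OP_KINDS:
            raise ValueError(f"unknown edit op kind {self.kind!r}")
        if self.count is not None and self.count <= 0:
            raise ValueError("count must be positive")
        for lm in (self.landmark, self.start_landmark, self.end_landmark):
            if lm is not None and not 4 <= len(lm) <= 6:
                raise ValueError(f"landmark {lm!r} must be 4-6 residues")


@dataclass
class EditScript:
    locus_id: str
    ops: list[EditOp] = field(default_factory=list)
    expected_final_length: Optional[int] = None
    note: str = ""


@dataclass
class EditReport:
    locus_id: str
    initial_length: int
    final_length: int
    deltas: list[int]  # per-op residue change (negative = removed)

    @property
    def total_delta(self) -> int:
        return self.final_length - self.initial_length


def _find_unique(seq: str, landmark: str, op_name: str) -> int:
    first = seq.find(landmark)
    if first < 0:
        raise EditError(f"{op_name}: landmark {landmark!r} absent")
    if seq.find(landmark, first + 1) >= 0:
        raise EditError(f"{op_name}: landmark {landmark!r} ambiguous (multiple hits)")
    return first


def _apply_op(seq: str, op: EditOp) -> str:
    if op.kind == "trim_n_terminal_to":
        idx = _find_unique(seq, op.landmark, op.kind)
        if idx == 0:
            raise EditError(
                f"trim_n_terminal_to: landmark {op.landmark!r} already at the "
                "N-terminus, nothing to trim"
            )
        return seq[idx:]
    if op.kind == "trim_n_terminal_count":
        if op.count >= len(seq):
            raise EditError("trim_n_terminal_count: count exceeds sequence length")
        return seq[op.count:]
    if op.kind == "excise":
        start = _find_unique(seq, op.start_landmark, "excise")
        end = _find_unique(seq, op.end_landmark, "excise")
        end_excl = end + len(op.end_landmark)
        if end_excl <= start:
            raise EditError("excise: start landmark after end landmark")
        return seq[:start] + seq[end_excl:]
    if op.kind == "replace_c_terminal":
        if not seq.endswith(op.old_suffix):
            raise EditError(
                f"replace_c_terminal: sequence does not end with {op.old_suffix!r}"
            )
        return seq[: len(seq) - len(op.old_suffix)] + op.new_suffix
    if op.kind == "remove_run":
        run = op.residue * op.count
        # the run must be maximal: not flanked by more of the same residue
        hits = []
        i = seq.find(run)
        while i >= 0:
            left_ok = i == 0 or seq[i - 1] != op.residue
            right_ok = i + op.count == len(seq) or seq[i + op.count] != op.residue
            if left_ok and right_ok:
                hits.append(i)
            i = seq.find(run, i + 1)
        if not hits:
            raise EditError(
                f"remove_run: no run of {op.count} x {op.residue!r} found"
            )
        if len(hits) > 1:
            raise EditError(f"remove_run: run of {op.count} x {op.residue!r} ambiguous")
        i = hits[0]
        return seq[:i] + seq[i + op.count:]
    raise AssertionError(op.kind)


def apply_edit_script(sequence: str, script: EditScript) -> tuple[str, EditReport]:
    """Apply a script, returning the edited sequence and residue accounting."""
    seq = sequence
    deltas: list[int] = []
    for op in script.ops:
        try:
            new = _apply_op(seq, op)
        except EditError as exc:
            raise EditError(f"{script.locus_id}: {exc}") from None
        deltas.append(len(new) - len(seq))
        seq = new
    if (
        script.expected_final_length is not None
        and len(seq) != script.expected_final_length
    ):
        raise EditError(
            f"{script.locus_id}: final length {len(seq)} != expected "
            f"{script.expected_final_length}"
        )
    report = EditReport(
        locus_id=script.locus_id,
        initial_length=len(sequence),
        final_length=len(seq),
        deltas=deltas,
    )
    return seq, report


# ---------------------------------------------------------------------------
# Packaged rice curation recipes

def parse_scripts_config(text: str) -> list[EditScript]:
    """Parse the plain-text script config (one op per line).

    Sections start with ``[name]``; ``expect_length N`` and ``note ...``
    lines set metadata; every other line is ``<kind> <args...>``.
    """
    scripts: list[EditScript] = []
    current: Optional[EditScript] = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = EditScript(locus_id=line[1:-1])
            scripts.append(current)
            continue
        if current is None:
            raise ValueError("op line before any [section] header")
        parts = line.split()
        key, args = parts[0], parts[1:]
        if key == "expect_length":
            current.expected_final_length = int(args[0])
        elif key == "note":
            current.note = " ".join(args)
        elif key == "trim_n_terminal_to":
            current.ops.append(EditOp(kind=key, landmark=args[0]))
        elif key == "trim_n_terminal_count":
            current.ops.append(EditOp(kind=key, count=int(args[0])))
        elif key == "excise":
            current.ops.append(
                EditOp(kind=key, start_landmark=args[0], end_landmark=args[1])
            )
        elif key == "replace_c_terminal":
            current.ops.append(
                EditOp(kind=key, old_suffix=args[0], new_suffix=args[1])
            )
        elif key == "remove_run":
            current.ops.append(EditOp(kind=key, residue=args[0], count=int(args[1])))
        else:
            raise ValueError(f"unknown config line {raw!r}")
    return scripts


def format_scripts_config(scripts: list[EditScript]) -> str:
    out: list[str] = []
    for s in scripts:
        out.append(f"[{s.locus_id}]")
        if s.expected_final_length is not None:
            out.append(f"expect_length {s.expected_final_length}")
        if s.note:
            out.append(f"note {s.note}")
        for op in s.ops:
            if op.kind == "trim_n_terminal_to":
                out.append(f"trim_n_terminal_to {op.landmark}")
            elif op.kind == "trim_n_terminal_count":
                out.append(f"trim_n_terminal_count {op.count}")
            elif op.kind == "excise":
                out.append(f"excise {op.start_landmark} {op.end_landmark}")
            elif op.kind == "replace_c_terminal":
                out.append(f"replace_c_terminal {op.old_suffix} {op.new_suffix}")
            elif op.kind == "remove_run":
                out.append(f"remove_run {op.residue} {op.count}")
        out.append("")
    return "\n".join(out)


def build_rice_scripts() -> list[EditScript]:
    """The six packaged curation recipes for the revised rice gene models."""
    text = (
        resources.files("serpinkit.data").joinpath("rice_scripts.cfg").read_text()
    )
    return parse_scripts_config(text)


#: database model lengths the packaged scripts expect to start from
DATABASE_MODEL_LENGTHS = {
    "OsSRP-QKG": 423,
    "OsSRP-LRS": 468,  # conforming 137 + 72 + 252 + 7 segment layout
    "OsSRP-PLP": 439,
    "OsSRP-PSG": 452,
    "OsSRP-PTY": 510,
    "OsSRP-PGY": 524,
}

#: expected intron counts for the curated gene models
EXPECTED_INTRONS = {"OsSRP-QKG": 0}
DEFAULT_INTRON_COUNT = 1


def validate_intron_count(declared: dict[str, int]) -> list[dict]:
    """Flag loci whose declared intron count differs from the curated model."""
    report = []
    for name, count in declared.items():
        expected = EXPECTED_INTRONS.get(name, DEFAULT_INTRON_COUNT)
        report.append(
            {
                "name": name,
                "declared": count,
                "expected": expected,
                "ok": count == expected,
            }
        )
    return report
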