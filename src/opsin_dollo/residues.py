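"""Residue-homology checks through a multiple alignment.

Functional opsins carry a lysine in the seventh transmembrane helix —
position 296 of bovine rhodopsin, hence "K296" — that forms the Schiff
base with the retinal chromophore.  Given an alignment containing a
reference sequence and the reference's ungapped coordinate of that
lysine, this module maps the coordinate to an alignment column and
classifies every other sequence at the homologous column:

* ``lysine_present`` — K at the column;
* ``lysine_absent`` — any other residue (ambiguity codes included,
  conservatively: the check demands a positive lysine);
* ``undetermined_truncated`` — gap at the column with no residues at all
  on one side of it, i.e. the sequence simply does not extend that far;
* ``undetermined_gap`` — gap at the column but flanking residues on both
  sides (an internal alignment gap).

The truncated/internal distinction mirrors how incomplete transcripts
are reported separately from complete sequences that genuinely lack the
residue.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "Call",
    "ResidueCall",
    "read_alignment",
    "map_reference_position",
    "classify_sequences",
    "summarize_calls",
    "calls_to_tsv",
]

GAP_CHARS = "-."
AMBIGUOUS = set("XBZJUO*")


class Call(enum.Enum):
    LYSINE_PRESENT = "lysine_present"
    LYSINE_ABSENT = "lysine_absent"
    UNDETERMINED_TRUNCATED = "undetermined_truncated"
    UNDETERMINED_GAP = "undetermined_gap"


@dataclass(frozen=True)
class ResidueCall:
    """Classification of one sequence at the homologous reference column."""

    seq_id: str
    column: int  # 1-based alignment column
    residue: str  # one-letter residue, or '-'
    call: Call
    complete: bool  # has residues on both sides of the column
    note: str = ""


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    return AlignIO.read(str(path), "fasta")


def _check_uniform(alignment: MultipleSeqAlignment) -> int:
    lengths = {len(rec.seq) for rec in alignment}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    if not lengths:
        raise ValueError("empty alignment")
    return lengths.pop()


def map_reference_position(
    alignment: MultipleSeqAlignment, reference_id: str, reference_position: int
) -> int:
    """Alignment column (1-based) holding the reference's Nth ungapped residue."""
    _check_uniform(alignment)
    for rec in alignment:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    else:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    if reference_position < 1:
        raise IndexError(f"reference_position must be ≥ 1, got {reference_position}")
    count = 0
    for col, ch in enumerate(ref, start=1):
        if ch not in GAP_CHARS:
            count += 1
            if count == reference_position:
                return col
    raise IndexError(
        f"reference_position {reference_position} beyond ungapped length {count} "
        f"of {reference_id!r}"
    )


def classify_sequences(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    reference_position: int,
    include_reference: bool = False,
) -> list[ResidueCall]:
    """One :class:`ResidueCall` per (non-reference) sequence."""
    column = map_reference_position(alignment, reference_id, reference_position)
    col = column - 1
    calls: list[ResidueCall] = []
    for rec in alignment:
        if rec.id == reference_id and not include_reference:
            continue
        seq = str(rec.seq)
        ch = seq[col].upper()
        upstream = any(c not in GAP_CHARS for c in seq[:col])
        downstream = any(c not in GAP_CHARS for c in seq[col + 1 :])
        complete = upstream and downstream
        note = ""
        if ch in GAP_CHARS:
            call = Call.UNDETERMINED_GAP if complete else Call.UNDETERMINED_TRUNCATED
            ch = "-"
        elif ch == "K":
            call = Call.LYSINE_PRESENT
        else:
            call = Call.LYSINE_ABSENT
            if ch in AMBIGUOUS:
                note = f"ambiguity code {ch!r} treated as lysine-absent"
                warnings.warn(f"{rec.id}: {note}", stacklevel=2)
        calls.append(ResidueCall(rec.id, column, ch, call, complete, note))
    return calls


def summarize_calls(calls: list[ResidueCall]) -> dict:
    """Count calls per category and flag sequences for matrix notes.

    Sequences lacking the lysine or undetermined at the column are the
    ones a presence matrix should mark with a cautionary note (the
    half-coloured-square convention).
    """
    counts = Counter(c.call.value for c in calls)
    summary = {call.value: counts.get(call.value, 0) for call in Call}
    flagged = sorted(c.seq_id for c in calls if c.call is not Call.LYSINE_PRESENT)
    return {"counts": summary, "flagged": flagged, "n": len(calls)}


def calls_to_tsv(calls: list[ResidueCall]) -> str:
    lines = ["seq_id\tcolumn\tresidue\tcall\tcomplete\tnote"]
    for c in calls:
        lines.append(
            f"{c.seq_id}\t{c.column}\t{c.residue}\t{c.call.value}\t{int(c.complete)}\t{c.note}"
        )
    return "\n".join(lines) + "\n"
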