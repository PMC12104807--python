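"""Family-by-clade presence/absence matrices.

The central container of the package: a small table recording, for each
gene family (rows) and each terminal clade of a species tree (columns),
whether the family is present, absent, or of uncertain status.  Uncertain
cells arise when the only supporting sequences fail a diagnostic test
(here: the opsin-defining K296 lysine) and are resolved to a binary state
by an explicit policy before any reconstruction.

On-disk dialect: tab-separated, first column ``family``, remaining columns
clade identifiers, cells ``1`` / ``0`` / ``?``.  An optional parallel
``#note`` syntax is not used; provenance notes live in memory only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "State",
    "UncertainPolicy",
    "PresenceMatrix",
    "MatrixError",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
]


class MatrixError(ValueError):
    """Base class for presence-matrix errors."""


class MatrixParseError(MatrixError):
    """A cell or header could not be interpreted."""


class MatrixValidationError(MatrixError):
    """The parsed table violates a structural invariant."""


class State(enum.Enum):
    """Presence state of one (family, clade) cell."""

    PRESENT = "1"
    ABSENT = "0"
    UNCERTAIN = "?"

    @classmethod
    def from_token(cls, token: str) -> "State":
        try:
            return cls(token.strip())
        except ValueError:
            raise MatrixParseError(f"unknown cell token {token!r}; expected 1, 0 or ?") from None


class UncertainPolicy(enum.Enum):
    """How ``?`` cells are resolved when a binary state is required.

    The primary analysis keeps uncertain families (sequences lacking the
    diagnostic lysine) as present; the alternate scenario drops them.
    """

    AS_PRESENT = "present"
    AS_ABSENT = "absent"

    def resolve(self, state: State) -> State:
        if state is not State.UNCERTAIN:
            return state
        return State.PRESENT if self is UncertainPolicy.AS_PRESENT else State.ABSENT


@dataclass
class PresenceMatrix:
    """Ordered binary/uncertain occurrence table with per-cell notes."""

    families: list[str]
    clades: list[str]
    cells: dict[tuple[str, str], State]
    notes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        for name, ids in (("family", self.families), ("clade", self.clades)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise MatrixValidationError(f"duplicate {name} identifier {i!r}")
                seen.add(i)
        for fam in self.families:
            for clade in self.clades:
                if (fam, clade) not in self.cells:
                    raise MatrixValidationError(f"missing cell ({fam!r}, {clade!r})")
        extra = set(self.cells) - {(f, c) for f in self.families for c in self.clades}
        if extra:
            raise MatrixValidationError(f"cells outside declared rows/columns: {sorted(extra)}")

    # -- access --------------------------------------------------------

    def state(self, family: str, clade: str) -> State:
        self._check_family(family)
        self._check_clade(clade)
        return self.cells[(family, clade)]

    def _check_clade(self, clade: str) -> None:
        if clade not in self.clades:
            raise KeyError(f"unknown clade {clade!r}; have {self.clades}")

    def _check_family(self, family: str) -> None:
        if family not in self.families:
            raise KeyError(f"unknown family {family!r}")

    def terminal_states(
        self, family: str, policy: UncertainPolicy = UncertainPolicy.AS_PRESENT
    ) -> dict[str, bool]:
        """Binary presence per clade for one family, after policy resolution."""
        self._check_family(family)
        return {
            clade: policy.resolve(self.cells[(family, clade)]) is State.PRESENT
            for clade in self.clades
        }

    def count_present(
        self,
        clade: str,
        family_subset: Sequence[str] | None = None,
        policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
    ) -> int:
        """Number of families (optionally restricted) present in a clade.

        Uncertain cells count according to ``policy``; the default mirrors
        the primary analysis, which retains families supported only by
        lysine-lacking sequences.
        """
        return self._count(clade, family_subset, policy, State.PRESENT)

    def count_absent(
        self,
        clade: str,
        family_subset: Sequence[str] | None = None,
        policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
    ) -> int:
        return self._count(clade, family_subset, policy, State.ABSENT)

    def count_uncertain(self, clade: str, family_subset: Sequence[str] | None = None) -> int:
        self._check_clade(clade)
        fams = self._subset(family_subset)
        return sum(1 for f in fams if self.cells[(f, clade)] is State.UNCERTAIN)

    def _count(
        self,
        clade: str,
        family_subset: Sequence[str] | None,
        policy: UncertainPolicy,
        target: State,
    ) -> int:
        self._check_clade(clade)
        fams = self._subset(family_subset)
        return sum(1 for f in fams if policy.resolve(self.cells[(f, clade)]) is target)

    def _subset(self, family_subset: Sequence[str] | None) -> list[str]:
        if family_subset is None:
            return self.families
        for f in family_subset:
            self._check_family(f)
        return list(family_subset)

    def present_clades(
        self, family: str, policy: UncertainPolicy = UncertainPolicy.AS_PRESENT
    ) -> list[str]:
        states = self.terminal_states(family, policy)
        return [c for c in self.clades if states[c]]

    # -- derivation ----------------------------------------------------

    def with_cell(self, family: str, clade: str, state: State) -> "PresenceMatrix":
        """Copy with one cell replaced (notes carried over)."""
        self._check_family(family)
        self._check_clade(clade)
        cells = dict(self.cells)
        cells[(family, clade)] = state
        return PresenceMatrix(list(self.families), list(self.clades), cells, dict(self.notes))

    def resolve(self, policy: UncertainPolicy) -> "PresenceMatrix":
        """Copy with every uncertain cell resolved by ``policy``."""
        cells = {k: policy.resolve(v) for k, v in self.cells.items()}
        return PresenceMatrix(list(self.families), list(self.clades), cells, dict(self.notes))

    def diff(self, other: "PresenceMatrix") -> list[tuple[str, str, State, State]]:
        """Cells that differ from ``other`` (same shape required)."""
        if self.families != other.families or self.clades != other.clades:
            raise MatrixValidationError("matrices have different row/column sets")
        out = []
        for f in self.families:
            for c in self.clades:
                a, b = self.cells[(f, c)], other.cells[(f, c)]
                if a is not b:
                    out.append((f, c, a, b))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.families == other.families
            and self.clades == other.clades
            and self.cells == other.cells
        )


def read_matrix(path: str | Path, dialect: str = "tsv") -> PresenceMatrix:
    """Read a presence matrix from a TSV file.

    Header row names the clades (first column literal ``family``); every
    following row is one family.  Raises :class:`MatrixParseError` with
    the row/column location on an unknown cell token and
    :class:`MatrixValidationError` on duplicate identifiers.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    text = Path(path).read_text()
    return parse_matrix(text)


def parse_matrix(text: str) -> PresenceMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError("empty matrix file")
    header = lines[0].split("\t")
    if not header or header[0] != "family":
        raise MatrixParseError(f"first header column must be 'family', got {header[:1]}")
    clades = header[1:]
    if not clades:
        raise MatrixParseError("no clade columns in header")
    families: list[str] = []
    cells: dict[tuple[str, str], State] = {}
    for row_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise MatrixParseError(
                f"row {row_no}: expected {len(header)} columns, got {len(parts)}"
            )
        fam = parts[0]
        families.append(fam)
        for col_no, token in enumerate(parts[1:]):
            try:
                cells[(fam, clades[col_no])] = State.from_token(token)
            except MatrixParseError as exc:
                raise MatrixParseError(
                    f"row {row_no}, column {clades[col_no]!r}: {exc}"
                ) from None
    return PresenceMatrix(families, clades, cells)


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_matrix` (round-trip safe)."""
    Path(path).write_text(format_matrix(matrix))


def format_matrix(matrix: PresenceMatrix) -> str:
    lines = ["family\t" + "\t".join(matrix.clades)]
    for fam in matrix.families:
        row = [fam] + [matrix.cells[(fam, c)].value for c in matrix.clades]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
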