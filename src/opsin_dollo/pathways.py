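"""Clade-level pathway-completeness aggregation.

Per-species annotation decisions are lifted to clade level under the
rule that annotating a gene in any one member species annotates it for
the whole group; umbrella groups (e.g. Xenacoelomorpha over Acoela,
Nemertodermatida and Xenoturbella) inherit presence from any subgroup.
Presence is boolean — paralog counts are not tracked at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hits import AnnotationDecision, Status
from .matrix import PresenceMatrix, State

__all__ = ["GroupMap", "aggregate_presence", "aggregate_matrix", "pathway_report", "PathwayCount"]


@dataclass
class GroupMap:
    """Species → group membership, with optional umbrella groups.

    ``species_to_groups`` assigns each species to one or more base
    groups; ``umbrellas`` maps an umbrella group to the base groups it
    contains.  Group order fixes matrix column order.
    """

    species_to_groups: dict[str, set[str]]
    umbrellas: dict[str, set[str]] = field(default_factory=dict)
    group_order: list[str] | None = None

    def __post_init__(self) -> None:
        base = set()
        for groups in self.species_to_groups.values():
            if not groups:
                raise ValueError("every species must map to at least one group")
            base |= groups
        for umbrella, subs in self.umbrellas.items():
            missing = subs - base
            if missing:
                raise ValueError(f"umbrella {umbrella!r} lists unknown subgroups {sorted(missing)}")
        if self.group_order is None:
            self.group_order = sorted(base) + sorted(self.umbrellas)
        declared = base | set(self.umbrellas)
        if set(self.group_order) != declared:
            raise ValueError("group_order must list every base and umbrella group exactly")

    @property
    def groups(self) -> list[str]:
        return list(self.group_order or [])

    def groups_for(self, unit: str) -> set[str]:
        """All groups containing ``unit`` (a species or a group name).

        A group contains itself, and an umbrella contains its subgroups —
        this makes aggregation of an already clade-level matrix a no-op.
        """
        if unit in self.species_to_groups:
            direct = set(self.species_to_groups[unit])
        elif unit in (self.group_order or []):
            direct = {unit}
        else:
            raise KeyError(f"unknown species or group {unit!r}")
        out = set(direct)
        for umbrella, subs in self.umbrellas.items():
            if direct & subs:
                out.add(umbrella)
        return out


def aggregate_presence(
    decisions_by_species: Mapping[str, Sequence[AnnotationDecision]],
    groups: GroupMap,
    gene_universe: Sequence[str],
) -> PresenceMatrix:
    """KO × group presence matrix from per-species annotation decisions.

    A cell is present iff at least one member species carries an
    ``annotated`` decision for that KO.  Unknown species raise, naming
    the offender.  With no decisions at all the matrix is all-absent
    over ``gene_universe``.
    """
    present: dict[tuple[str, str], bool] = {}
    for species, decisions in decisions_by_species.items():
        if species not in groups.species_to_groups:
            raise KeyError(f"species {species!r} not in group map")
        for d in decisions:
            if d.status is not Status.ANNOTATED or d.ko is None:
                continue
            for g in groups.groups_for(species):
                present[(d.ko, g)] = True
    cells = {
        (ko, g): State.PRESENT if present.get((ko, g)) else State.ABSENT
        for ko in gene_universe
        for g in groups.groups
    }
    return PresenceMatrix(list(gene_universe), groups.groups, cells)


def aggregate_matrix(matrix: PresenceMatrix, groups: GroupMap) -> PresenceMatrix:
    """Lift a KO × (species or group) matrix to KO × group.

    Idempotent: if the columns are already the map's groups, the result
    equals the input.
    """
    cells: dict[tuple[str, str], State] = {
        (ko, g): State.ABSENT for ko in matrix.families for g in groups.groups
    }
    for ko in matrix.families:
        for unit in matrix.clades:
            if matrix.state(ko, unit) is State.PRESENT:
                for g in groups.groups_for(unit):
                    cells[(ko, g)] = State.PRESENT
    return PresenceMatrix(list(matrix.families), groups.groups, cells)


@dataclass(frozen=True)
class PathwayCount:
    """Completeness of one pathway in one group."""

    pathway: str
    group: str
    n_total: int
    n_present: int
    absent: tuple[str, ...]

    @property
    def n_absent(self) -> int:
        return len(self.absent)


def pathway_report(
    matrix: PresenceMatrix, pathway_partition: Mapping[str, str]
) -> dict[tuple[str, str], PathwayCount]:
    """Per-(pathway, group) completeness counts with absentee lists.

    ``pathway_partition`` must assign every matrix row to exactly one
    pathway; a gene shared between reference pathways appears as one row
    per pathway (distinct row ids), as in the source table layout.
    """
    missing = [f for f in matrix.families if f not in pathway_partition]
    if missing:
        raise ValueError(f"rows not assigned to any pathway: {missing}")
    pathways = sorted(set(pathway_partition[f] for f in matrix.families))
    report: dict[tuple[str, str], PathwayCount] = {}
    for pw in pathways:
        rows = [f for f in matrix.families if pathway_partition[f] == pw]
        for group in matrix.clades:
            absent = tuple(f for f in rows if matrix.state(f, group) is not State.PRESENT)
            report[(pw, group)] = PathwayCount(
                pw, group, len(rows), len(rows) - len(absent), absent
            )
    return report


def report_to_tsv(report: Mapping[tuple[str, str], PathwayCount]) -> str:
    lines = ["pathway\tgroup\tn_total\tn_present\tn_absent\tabsent_genes"]
    for (pw, group), c in sorted(report.items()):
        lines.append(
            f"{pw}\t{group}\t{c.n_total}\t{c.n_present}\t{c.n_absent}\t{','.join(c.absent)}"
        )
    return "\n".join(lines) + "\n"
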