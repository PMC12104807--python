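"""Similarity-search hit tables and the annotation decision cascade.

The package consumes 12-column tabular hit files (the BLAST/DIAMOND
``outfmt 6`` dialect) produced by an external search; it never runs the
search itself.  Its contribution is the decision machinery on top:

* best-hit reduction with a documented, logged tie-break;
* the reciprocal opsin filter — a candidate survives only if at least
  one of its top-k reciprocal hits is a known opsin;
* the three-tier pathway annotation: shared accession number first, then
  unambiguous protein name, then shared sequence-cluster membership.

Subject metadata (display name, opsin flag, cluster id, accession)
travels in a side table keyed by subject id.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OUTFMT6_COLUMNS",
    "HitTable",
    "SubjectInfo",
    "AnnotationDecision",
    "Status",
    "Tier",
    "PathwayEntry",
    "read_hit_table",
    "read_subject_metadata",
    "evalue_prefilter",
    "best_hit_per_query",
    "reciprocal_opsin_filter",
    "kegg_tiered_annotation",
]

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_FLOAT_COLS = {"pident": float, "evalue": float, "bitscore": float}
_INT_COLS = ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"]


@dataclass
class HitTable:
    """Thin wrapper around a 12-column hit DataFrame."""

    df: pd.DataFrame
    tie_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.df.columns) != OUTFMT6_COLUMNS:
            raise ValueError(
                f"hit table must have columns {OUTFMT6_COLUMNS}, got {list(self.df.columns)}"
            )
        if len(self.df):
            if (self.df["evalue"] < 0).any():
                raise ValueError("negative e-value in hit table")
            if not self.df["bitscore"].map(lambda x: x == x and abs(x) != float("inf")).all():
                raise ValueError("non-finite bit score in hit table")
            if (self.df["qseqid"].astype(str) == "").any() or (
                self.df["sseqid"].astype(str) == ""
            ).any():
                raise ValueError("empty query or subject id")

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence]) -> "HitTable":
        df = pd.DataFrame(list(rows), columns=OUTFMT6_COLUMNS)
        if len(df):
            for c in _INT_COLS:
                df[c] = df[c].astype(int)
            for c, t in _FLOAT_COLS.items():
                df[c] = df[c].astype(t)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path: str | Path, header: bool = False) -> None:
        self.df.to_csv(path, sep="\t", index=False, header=header)

    def to_tsv(self, header: bool = False) -> str:
        return self.df.to_csv(sep="\t", index=False, header=header)


def read_hit_table(path: str | Path) -> HitTable:
    """Read an ``outfmt 6`` table; a header line naming ``qseqid`` is optional."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    has_header = first.split("\t")[0].strip() == "qseqid"
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else OUTFMT6_COLUMNS,
        comment="#",
    )
    df.columns = OUTFMT6_COLUMNS
    return HitTable(df)


@dataclass(frozen=True)
class SubjectInfo:
    """Side-table entry for one reference subject."""

    subject_id: str
    name: str
    is_opsin: bool
    cluster: str
    accession: str


def read_subject_metadata(path: str | Path) -> dict[str, SubjectInfo]:
    """TSV with columns: subject_id, name, is_opsin (0/1), cluster, accession."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for rec in df.itertuples(index=False):
        out[rec.subject_id] = SubjectInfo(
            rec.subject_id, rec.name, bool(int(rec.is_opsin)), rec.cluster, rec.accession
        )
    return out


def write_subject_metadata(metadata: Mapping[str, SubjectInfo], path: str | Path) -> None:
    rows = [
        {
            "subject_id": m.subject_id,
            "name": m.name,
            "is_opsin": int(m.is_opsin),
            "cluster": m.cluster,
            "accession": m.accession,
        }
        for m in metadata.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Status(enum.Enum):
    ANNOTATED = "annotated"
    REMOVED = "removed"
    UNRESOLVED = "unresolved"


class Tier(enum.Enum):
    ACCESSION = "accession"
    NAME = "name"
    CLUSTER = "cluster"
    CANDIDATE_FILTER = "candidate_filter"


@dataclass
class AnnotationDecision:
    """Outcome of one protein through a filtering/annotation rule."""

    protein: str
    status: Status
    tier: Tier | None
    evidence: list[dict] = field(default_factory=list)
    ko: str | None = None
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "status": self.status.value,
            "tier": self.tier.value if self.tier else None,
            "ko": self.ko,
            "reason": self.reason,
            "evidence": self.evidence,
        }


def evalue_prefilter(hits: HitTable, threshold: float = 1e-5) -> HitTable:
    """Retain rows with e-value at or below the cutoff (default 1e-5,
    the standard sensitive-search setting)."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return HitTable(hits.df[hits.df["evalue"] <= threshold].reset_index(drop=True))


def _ranked(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic hit ranking: bit score desc, e-value asc, subject id lex."""
    return df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )


def best_hit_per_query(hits: HitTable) -> HitTable:
    """One maximal-bit-score row per query.

    Ties on bit score break by lower e-value, then lexicographically
    smaller subject id; every tie actually broken is appended to the
    returned table's ``tie_log``.  An empty table maps to an empty table.
    """
    if not len(hits):
        return HitTable(hits.df.copy())
    ranked = _ranked(hits.df)
    tie_log: list[dict] = []
    for q, grp in ranked.groupby("qseqid", sort=False):
        top = grp.iloc[0]
        tied = grp[(grp["bitscore"] == top["bitscore"]) & (grp["sseqid"] != top["sseqid"])]
        if len(tied):
            tie_log.append(
                {
                    "query": q,
                    "kept": top["sseqid"],
                    "tied_subjects": sorted(tied["sseqid"]),
                    "bitscore": float(top["bitscore"]),
                }
            )
    best = ranked.groupby("qseqid", sort=False).head(1).reset_index(drop=True)
    return HitTable(best, tie_log)


def _top_k(df: pd.DataFrame, k: int) -> pd.DataFrame:
    return _ranked(df).groupby("qseqid", sort=False).head(k)


def reciprocal_opsin_filter(
    candidates: Sequence[str],
    back_hits: HitTable,
    metadata: Mapping[str, SubjectInfo],
    k: int = 3,
) -> list[AnnotationDecision]:
    """Keep a candidate iff ≥1 of its top-k reciprocal hits is an opsin.

    The back-hit table is truncated to the k best rows per query (same
    ranking as :func:`best_hit_per_query`); candidates with no hits at
    all are removed with reason ``"no hits"``.
    """
    top = _top_k(back_hits.df, k)
    decisions: list[AnnotationDecision] = []
    for cand in candidates:
        rows = top[top["qseqid"] == cand]
        if not len(rows):
            decisions.append(
                AnnotationDecision(cand, Status.REMOVED, Tier.CANDIDATE_FILTER, [], reason="no hits")
            )
            continue
        evidence = []
        any_opsin = False
        for rec in rows.itertuples(index=False):
            info = metadata.get(rec.sseqid)
            is_opsin = bool(info and info.is_opsin)
            any_opsin = any_opsin or is_opsin
            evidence.append(
                {"subject": rec.sseqid, "bitscore": float(rec.bitscore), "is_opsin": is_opsin}
            )
        status = Status.ANNOTATED if any_opsin else Status.REMOVED
        reason = "" if any_opsin else f"no opsin among top-{k} reciprocal hits"
        decisions.append(
            AnnotationDecision(cand, status, Tier.CANDIDATE_FILTER, evidence, reason=reason)
        )
    return decisions


@dataclass
class PathwayEntry:
    """One KEGG-orthology gene: identifiers its members may carry.

    ``names`` is the explicit allow-list for the name tier; strings in
    ``ambiguous_names`` are documented deny-listed labels that must never
    fire (e.g. a bare family name shared by several paralogs).
    """

    ko: str
    accessions: set[str]
    names: set[str] = field(default_factory=set)
    ambiguous_names: set[str] = field(default_factory=set)
    clusters: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"{self.ko}: pathway entry with empty accession set")
        self.names = {n for n in self.names if n not in self.ambiguous_names}


def kegg_tiered_annotation(
    proteome_hits: HitTable,
    metadata: Mapping[str, SubjectInfo],
    pathway_db: Mapping[str, PathwayEntry],
) -> list[AnnotationDecision]:
    """Three-tier annotation extension over best hits.

    For each query protein's best hit, the first tier that fires wins:

    1. *accession* — the hit's accession belongs to a pathway gene;
    2. *name* — the hit's display name matches an allow-listed canonical
       name exactly (never a deny-listed ambiguous label);
    3. *cluster* — the hit shares a sequence cluster with a pathway gene.

    ``proteome_hits`` should already be best-hit reduced; if not, the
    reduction is applied here.  Proteins matching no tier are reported
    unresolved.  The pass is single-shot: cluster extension does not
    iterate over newly annotated proteins.
    """
    best = best_hit_per_query(proteome_hits)
    decisions: list[AnnotationDecision] = []
    for rec in best.df.itertuples(index=False):
        info = metadata.get(rec.sseqid)
        evidence = [{"subject": rec.sseqid, "bitscore": float(rec.bitscore)}]
        decision = AnnotationDecision(rec.qseqid, Status.UNRESOLVED, None, evidence)
        if info is not None:
            for ko, entry in pathway_db.items():
                if info.accession in entry.accessions:
                    decision = AnnotationDecision(
                        rec.qseqid, Status.ANNOTATED, Tier.ACCESSION, evidence, ko=ko
                    )
                    break
            else:
                for ko, entry in pathway_db.items():
                    if info.name in entry.names:
                        decision = AnnotationDecision(
                            rec.qseqid, Status.ANNOTATED, Tier.NAME, evidence, ko=ko
                        )
                        break
                else:
                    for ko, entry in pathway_db.items():
                        if info.cluster in entry.clusters:
                            decision = AnnotationDecision(
                                rec.qseqid, Status.ANNOTATED, Tier.CLUSTER, evidence, ko=ko
                            )
                            break
        decisions.append(decision)
    return decisions


def decisions_to_json(decisions: Sequence[AnnotationDecision]) -> str:
    return json.dumps([d.to_dict() for d in decisions], indent=2, sort_keys=True)


def decisions_to_tsv(decisions: Sequence[AnnotationDecision]) -> str:
    lines = ["protein\tstatus\ttier\tko\treason"]
    for d in decisions:
        lines.append(
            "\t".join(
                [d.protein, d.status.value, d.tier.value if d.tier else "", d.ko or "", d.reason]
            )
        )
    return "\n".join(lines) + "\n"
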