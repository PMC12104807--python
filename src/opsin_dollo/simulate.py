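"""Synthetic inputs with planted ground truth.

Every pipeline stage can be exercised offline: this module fabricates
presence matrices evolved under the single-gain/irreversible-loss model,
multiple alignments with a planted homologous lysine column, and
similarity-search hit tables with known opsin/non-opsin labels.  Each
generator threads a single integer seed through one numpy Generator and
logs the truth it planted, so outputs are byte-identical under a fixed
seed and every downstream inference can be checked against the log.

Realism is not the goal — identifiability of the planted truth is.
Alignments use a uniform 20-letter amino-acid alphabet; hit tables carry
strictly ordered bit scores unless ties are forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hits import HitTable, OUTFMT6_COLUMNS, SubjectInfo
from .matrix import PresenceMatrix, State
from .trees import CladeTree

__all__ = [
    "DolloTruth",
    "AlignmentTruth",
    "HitTruth",
    "simulate_dollo_matrix",
    "make_alignment_fixture",
    "make_hit_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DolloTruth:
    """Events actually applied by :func:`simulate_dollo_matrix`."""

    seed: int
    tree_newick: str
    gain_node: dict[str, str]
    loss_branches: dict[str, list[str]]

    @property
    def n_losses(self) -> int:
        return sum(len(v) for v in self.loss_branches.values())

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "tree": self.tree_newick,
            "gain_node": dict(self.gain_node),
            "loss_branches": {k: list(v) for k, v in self.loss_branches.items()},
            "n_losses": self.n_losses,
        }


def simulate_dollo_matrix(
    tree: CladeTree,
    n_families: int,
    loss_prob: float,
    seed: int,
    family_prefix: str = "fam",
) -> tuple[PresenceMatrix, DolloTruth]:
    """Evolve families under single gain + irreversible loss.

    Each family gains at a uniformly chosen node, then every branch below
    a still-present node loses independently with ``loss_prob``; lineages
    below a loss stay absent (no regain).  Families that end up absent
    from every terminal are discarded and regenerated so the emitted
    matrix always has one present cell per family.
    """
    if not 0 <= loss_prob < 1:
        raise ValueError(f"loss_prob must be in [0, 1), got {loss_prob}")
    rng = np.random.default_rng(seed)
    node_order = tree.postorder()  # fixed order → reproducible choice
    gains: dict[str, str] = {}
    losses: dict[str, list[str]] = {}
    cells: dict[tuple[str, str], State] = {}
    families: list[str] = []

    for i in range(n_families):
        fam = f"{family_prefix}{i + 1}"
        while True:
            gain = node_order[rng.integers(len(node_order))]
            fam_losses: list[str] = []
            present: set[str] = set()

            def descend(node: str, alive: bool) -> None:
                if alive and node != gain and rng.random() < loss_prob:
                    fam_losses.append(node)
                    alive = False
                if tree.is_leaf(node) and alive:
                    present.add(node)
                for child in tree.children(node):
                    descend(child, alive)

            descend(gain, True)
            if present:
                break
        gains[fam] = gain
        losses[fam] = fam_losses
        families.append(fam)
        for leaf in tree.leaves:
            cells[(fam, leaf)] = State.PRESENT if leaf in present else State.ABSENT

    matrix = PresenceMatrix(families, list(tree.leaves), cells)
    truth = DolloTruth(seed, tree.to_newick(), gains, losses)
    return matrix, truth


@dataclass
class AlignmentTruth:
    """Planted features of a synthetic alignment."""

    seed: int
    reference_id: str
    lysine_column: int  # 1-based alignment column
    reference_position: int  # 1-based ungapped position in the reference
    substituted: list[str]
    truncated: list[str]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "reference_id": self.reference_id,
            "lysine_column": self.lysine_column,
            "reference_position": self.reference_position,
            "substituted": list(self.substituted),
            "truncated": list(self.truncated),
        }


def make_alignment_fixture(
    n_seqs: int = 5,
    length: int = 120,
    lysine_column: int = 60,
    truncate_ids: Sequence[str] = (),
    substitute_ids: Sequence[str] = (),
    seed: int = 0,
    ids: Sequence[str] | None = None,
    reference_id: str | None = None,
    gap_prob: float = 0.05,
) -> tuple[MultipleSeqAlignment, AlignmentTruth]:
    """Aligned FASTA content with a planted homologous lysine column.

    The first sequence is the (gapless) reference and carries K at
    ``lysine_column``; so does every other sequence except those in
    ``substitute_ids`` (a non-lysine residue there) and ``truncate_ids``
    (gap-filled from before the column to the end, emulating incomplete
    transcripts).  Random internal gaps are sprinkled over the remaining
    columns of non-reference sequences.
    """
    if lysine_column > length or lysine_column < 1:
        raise ValueError("lysine_column must lie within the alignment length")
    if ids is None:
        ids = [f"seq_{i + 1}" for i in range(n_seqs)]
    if len(ids) != n_seqs:
        raise ValueError("ids length must equal n_seqs")
    reference_id = reference_id or ids[0]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among sequence ids")
    overlap = set(truncate_ids) & set(substitute_ids)
    if overlap:
        raise ValueError(f"ids both truncated and substituted: {sorted(overlap)}")
    for sid in list(truncate_ids) + list(substitute_ids):
        if sid not in ids:
            raise ValueError(f"unknown sequence id {sid!r}")
        if sid == reference_id:
            raise ValueError("the reference cannot be truncated or substituted")

    rng = np.random.default_rng(seed)
    col = lysine_column - 1
    records = []
    for sid in ids:
        residues = [AMINO_ACIDS[j] for j in rng.integers(len(AMINO_ACIDS), size=length)]
        residues[col] = "K"
        if sid == reference_id:
            records.append(SeqRecord(Seq("".join(residues)), id=sid, description=""))
            continue
        if sid in substitute_ids:
            non_k = AMINO_ACIDS.replace("K", "")
            residues[col] = non_k[rng.integers(len(non_k))]
        # random internal gaps away from the diagnostic column
        for j in range(length):
            if j != col and rng.random() < gap_prob:
                residues[j] = "-"
        if sid in truncate_ids:
            cut = int(rng.integers(max(1, col // 2), col))  # end before the column
            for j in range(cut, length):
                residues[j] = "-"
        records.append(SeqRecord(Seq("".join(residues)), id=sid, description=""))

    aln = MultipleSeqAlignment(records)
    truth = AlignmentTruth(
        seed,
        reference_id,
        lysine_column,
        lysine_column,  # reference is gapless: column == ungapped position
        sorted(substitute_ids),
        sorted(truncate_ids),
    )
    return aln, truth


@dataclass
class HitTruth:
    """Planted labels of a synthetic hit-table pair."""

    seed: int
    is_opsin: dict[str, bool]  # candidate protein → true label
    opsin_in_top_k: list[str]  # candidates that received ≥1 opsin back-hit in top k
    k: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "is_opsin": dict(self.is_opsin),
            "opsin_in_top_k": list(self.opsin_in_top_k),
            "k": self.k,
        }


def make_hit_fixture(
    n_true_opsins: int = 10,
    n_decoys: int = 10,
    k: int = 3,
    noise_rate: float = 0.0,
    seed: int = 0,
    force_ties: bool = False,
) -> tuple[HitTable, HitTable, dict[str, SubjectInfo], HitTruth]:
    """Forward + back-hit tables over candidates with known labels.

    Forward table: one bait query per candidate protein, so the best-hit
    reduction recovers exactly the candidate set.  Back-hit table: each
    candidate hits ``k`` reference subjects; true opsins receive at least
    one opsin subject among them with probability ``1 - noise_rate``,
    decoys never do.  Bit scores are strictly ordered within each query
    unless ``force_ties`` plants one exact tie for exercising the
    documented tie-break.
    """
    if not 0 <= noise_rate < 1:
        raise ValueError(f"noise_rate must be in [0, 1), got {noise_rate}")
    rng = np.random.default_rng(seed)

    candidates = [f"opsin_cand_{i + 1}" for i in range(n_true_opsins)] + [
        f"decoy_cand_{i + 1}" for i in range(n_decoys)
    ]
    labels = {c: c.startswith("opsin_") for c in candidates}

    metadata: dict[str, SubjectInfo] = {}
    n_ref = max(k + 1, 6)
    opsin_refs, other_refs = [], []
    for i in range(n_ref):
        sid = f"ref_opsin_{i + 1}"
        metadata[sid] = SubjectInfo(
            sid, f"Opsin homolog {i + 1}", True, f"cluster_ops_{i % 3 + 1}", f"OPS{i + 1:04d}"
        )
        opsin_refs.append(sid)
        sid = f"ref_other_{i + 1}"
        metadata[sid] = SubjectInfo(
            sid, f"Non-opsin GPCR {i + 1}", False, f"cluster_oth_{i % 3 + 1}", f"OTH{i + 1:04d}"
        )
        other_refs.append(sid)

    def row(q: str, s: str, bit: float, ev: float) -> list:
        return [q, s, 90.0, 250, 10, 1, 1, 250, 1, 250, ev, bit]

    forward_rows, back_rows = [], []
    opsin_in_top_k: list[str] = []
    for idx, cand in enumerate(candidates):
        forward_rows.append(row(f"bait_{idx + 1}", cand, 300.0 - idx, 1e-80))
        # choose k back-hit subjects
        if labels[cand] and rng.random() >= noise_rate:
            n_ops = int(rng.integers(1, k + 1))
            opsin_in_top_k.append(cand)
        else:
            n_ops = 0
        subjects = list(rng.choice(opsin_refs, size=n_ops, replace=False)) + list(
            rng.choice(other_refs, size=k - n_ops, replace=False)
        )
        rng.shuffle(subjects)
        base = 200.0 + float(rng.integers(0, 50))
        for rank, s in enumerate(subjects):
            bit = base - 5.0 * rank
            if force_ties and idx == 0 and rank == 1:
                bit = base  # exact tie with rank 0
            back_rows.append(row(cand, s, bit, 10.0 ** -(60 - rank - (1 if force_ties and idx == 0 and rank == 1 else 0))))

    forward = HitTable.from_rows(forward_rows)
    back = HitTable.from_rows(back_rows)
    truth = HitTruth(seed, labels, sorted(opsin_in_top_k), k)
    return forward, back, metadata, truth
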