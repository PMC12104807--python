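"""Packaged fixtures: the opsin presence matrices, the phototransduction
annotation table, per-family reconstruction configs, and a synthetic
alignment demonstrating the K296 check.

The opsin matrix encodes, at the granularity of five terminal clades
(Cnidaria, Xenacoelomorpha, Protostomia, Chordata, Ambulacraria), the
published family distributions: presence at a terminal means any sampled
descendant lineage retains the family.  The xenopsin cell for
Xenacoelomorpha is ``uncertain`` because neither supporting sequence
carries the diagnostic K296 lysine; the main analysis scores it present,
the alternate variant absent, and the two packaged matrices differ in
exactly that cell.

The phototransduction table transcribes the fly (rhabdomeric) and
vertebrate (ciliary) KEGG reference pathways — 18 KEGG-orthology genes
each — against Xenacoelomorpha, Chordata and Protostomia.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml
from Bio.Align import MultipleSeqAlignment

from .dollo import FamilyConfig
from .matrix import PresenceMatrix, State, parse_matrix
from .simulate import AlignmentTruth, make_alignment_fixture
from .trees import CladeTree, builtin_tree

__all__ = [
    "opsin_matrix_main",
    "opsin_matrix_xenopsin_absent",
    "MatrixFixtureSet",
    "fixture_set",
    "PhototransductionTable",
    "phototransduction_table",
    "packaged_configs",
    "packaged_alignment",
    "REFERENCE_ID",
    "K296_POSITION",
    "OPSIN_FAMILIES",
    "TERMINAL_CLADES",
]

OPSIN_FAMILIES = [
    "anthozoa_I",
    "chaopsin",
    "xenopsin",
    "c_opsin",
    "r_opsin_canonical",
    "r_opsin_noncanonical",
    "go_opsin",
    "neuropsin",
    "rgr_retinochrome",
    "bathyopsin",
    "xeno_specific",
]

TERMINAL_CLADES = ["Cnidaria", "Xenacoelomorpha", "Protostomia", "Chordata", "Ambulacraria"]

#: id of the embedded synthetic rhodopsin-like reference (see packaged_alignment)
REFERENCE_ID = "REF_RHODOPSIN_SYNTH"
#: the conserved retinal-binding lysine coordinate, 1-based and ungapped
K296_POSITION = 296


def _read_data(name: str) -> str:
    return resources.files("opsin_dollo.data").joinpath(name).read_text()


def opsin_matrix_main() -> PresenceMatrix:
    """Opsin family × clade matrix, xenopsin kept in Xenacoelomorpha."""
    m = parse_matrix(_read_data("opsin_matrix_main.tsv"))
    m.notes[("xenopsin", "Xenacoelomorpha")] = (
        "supported only by sequences lacking K296 (one complete, one truncated)"
    )
    return m


def opsin_matrix_xenopsin_absent() -> PresenceMatrix:
    """Variant scoring xenopsin absent in Xenacoelomorpha (lysine-less
    sequences discounted); differs from the main matrix in that one cell."""
    return parse_matrix(_read_data("opsin_matrix_xenopsin_absent.tsv"))


@dataclass
class MatrixFixtureSet:
    opsin_matrix_main: PresenceMatrix
    opsin_matrix_xenopsin_absent: PresenceMatrix
    phototransduction_matrix: PresenceMatrix


def fixture_set() -> MatrixFixtureSet:
    return MatrixFixtureSet(
        opsin_matrix_main(),
        opsin_matrix_xenopsin_absent(),
        phototransduction_table().matrix,
    )


@dataclass
class PhototransductionTable:
    """KO × clade presence with the pathway partition and display names.

    Row ids are ``pathway/KO`` so a gene shared by both reference
    pathways (e.g. calmodulin) keeps one row per pathway.
    """

    matrix: PresenceMatrix
    pathway_of: dict[str, str]
    gene_names: dict[str, str]

    def rows(self, pathway: str) -> list[str]:
        return [f for f in self.matrix.families if self.pathway_of[f] == pathway]


def phototransduction_table() -> PhototransductionTable:
    lines = [ln for ln in _read_data("phototransduction_table.tsv").splitlines() if ln.strip()]
    header = lines[0].split("\t")
    clades = header[3:]
    families: list[str] = []
    cells: dict[tuple[str, str], State] = {}
    pathway_of: dict[str, str] = {}
    gene_names: dict[str, str] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        pathway, ko, gene = parts[0], parts[1], parts[2]
        row_id = f"{pathway}/{ko}"
        families.append(row_id)
        pathway_of[row_id] = pathway
        gene_names[row_id] = gene
        for clade, token in zip(clades, parts[3:]):
            cells[(row_id, clade)] = State.PRESENT if token == "1" else State.ABSENT
    return PhototransductionTable(PresenceMatrix(families, clades, cells), pathway_of, gene_names)


def packaged_configs(hypothesis: str) -> dict[str, FamilyConfig]:
    """Family configurations for one of the builtin hypotheses.

    Shared across hypotheses: the xenacoelomorph-specific opsins are
    pinned to the bilaterian ancestor and their absences in lineages
    retaining canonical r-opsins are homology-suppressed.  Hypothesis
    blocks add duplication bookkeeping tied to nodes of that topology.
    """
    raw = yaml.safe_load(_read_data("family_configs.yaml"))
    if hypothesis not in raw and hypothesis != "shared":
        raise KeyError(
            f"no packaged configs for {hypothesis!r}; have {sorted(k for k in raw if k != 'shared')}"
        )
    merged: dict[str, dict] = {}
    for block in ("shared", hypothesis):
        for family, kv in (raw.get(block) or {}).items():
            merged.setdefault(family, {}).update(kv)
    out: dict[str, FamilyConfig] = {}
    for family, kv in merged.items():
        dup = kv.get("duplication_parent")
        out[family] = FamilyConfig(
            family=family,
            gain_override=kv.get("gain_override"),
            surrogate_of=kv.get("surrogate_of"),
            duplication_parent=tuple(dup) if dup else None,
        )
    return out


_ALIGNMENT_SEED = 20250526  # fixed: the fixture is data, not an experiment knob


def packaged_alignment() -> tuple[MultipleSeqAlignment, AlignmentTruth]:
    """Synthetic alignment demonstrating the K296 classification.

    Four sequences against a gapless synthetic rhodopsin-like reference
    (348 columns, lysine at position 296): a complete sequence with a
    substitution at the lysine column, a sequence truncated before the
    column, and two intact controls.  The first two emulate the
    complete-but-lysine-less vs. incomplete cases that make xenopsin
    presence uncertain.
    """
    ids = [
        REFERENCE_ID,
        "xenopsin_complete_nolys_synth",
        "xenopsin_truncated_synth",
        "opsin_control_a_synth",
        "opsin_control_b_synth",
    ]
    return make_alignment_fixture(
        n_seqs=len(ids),
        length=348,
        lysine_column=K296_POSITION,
        truncate_ids=["xenopsin_truncated_synth"],
        substitute_ids=["xenopsin_complete_nolys_synth"],
        seed=_ALIGNMENT_SEED,
        ids=ids,
        reference_id=REFERENCE_ID,
    )


def builtin_trees() -> dict[str, CladeTree]:
    return {name: builtin_tree(name) for name in ("nephrozoa", "xenambulacraria")}
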