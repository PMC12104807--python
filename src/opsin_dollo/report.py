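"""Consolidated reproduction report.

One call runs the whole desk-scale analysis on the packaged fixtures —
both gain/loss scenarios on both species-tree hypotheses, the ancestral
bilaterian repertoire queries, the phototransduction completeness table,
and the K296 residue-check demonstration — and labels every computed
number against its published reference value.  The report is emitted as
a machine-readable dict (JSON-ready) plus a Markdown rendering; a
mismatch list makes the success criterion explicit (empty ⇔ exit 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import fixtures
from .dollo import ancestral_repertoire, compare_hypotheses, reconstruct_scenario
from .matrix import UncertainPolicy
from .pathways import pathway_report
from .residues import Call, classify_sequences, summarize_calls
from .trees import BILATERIAN_ANCESTOR, builtin_tree

__all__ = ["reproduce_paper", "ReproductionReport"]

#: Published reference values the report compares against.
EXPECTED = {
    "losses_main": {"xenambulacraria": 11, "nephrozoa": 4},
    "losses_xenopsin_absent": {"xenambulacraria": 10, "nephrozoa": 5},
    "parallel_main": {"xenambulacraria": 3, "nephrozoa": 1},
    "parallel_xenopsin_absent": {"xenambulacraria": 2, "nephrozoa": 1},
    "repertoire_bilateria": {"nephrozoa": 7, "xenambulacraria": 11},
    "xenacoelomorpha_opsin_types": 6,
    "fly_absent_xenacoelomorpha": 4,
    "fly_absent_chordata": 5,
    "vertebrate_present_xenacoelomorpha": 5,
}


@dataclass
class ReproductionReport:
    results: dict
    mismatches: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def to_json(self) -> str:
        return json.dumps(
            {"results": self.results, "mismatches": self.mismatches, "ok": self.ok},
            indent=2,
            sort_keys=True,
        )

    def to_markdown(self) -> str:
        r = self.results
        lines = [
            "# Opsin gain/loss reproduction report",
            "",
            "## Loss totals (Dollo reconstruction, packaged opsin matrix)",
            "",
            "| scenario | Xenambulacraria | Nephrozoa |",
            "|---|---|---|",
            f"| main (xenopsin retained) | {r['losses_main']['xenambulacraria']} | "
            f"{r['losses_main']['nephrozoa']} |",
            f"| xenopsin absent in Xenacoelomorpha | "
            f"{r['losses_xenopsin_absent']['xenambulacraria']} | "
            f"{r['losses_xenopsin_absent']['nephrozoa']} |",
            "",
            f"Most parsimonious hypothesis (main matrix): **{', '.join(r['winners_main'])}**",
            "",
            "## Parallel losses (families lost in ≥2 terminal clades)",
            "",
            f"- main: {r['parallel_main']}",
            f"- xenopsin absent: {r['parallel_xenopsin_absent']}",
            "",
            "## Ancestral bilaterian opsin repertoire",
            "",
            f"- Nephrozoa scenario: {r['repertoire_bilateria']['nephrozoa']} families "
            f"({', '.join(sorted(r['repertoire_families']['nephrozoa']))})",
            f"- Xenambulacraria scenario: {r['repertoire_bilateria']['xenambulacraria']} families",
            "",
            "## Xenacoelomorpha opsins",
            "",
            f"- distinct opsin types present: {r['xenacoelomorpha_opsin_types']}",
            "",
            "## Phototransduction pathway completeness",
            "",
            f"- fly pathway, Xenacoelomorpha: {r['fly_present_xenacoelomorpha']}/18 present "
            f"(absent: {', '.join(r['fly_absent_genes_xenacoelomorpha'])})",
            f"- fly pathway, Chordata: missing {r['fly_absent_chordata']} genes",
            f"- vertebrate pathway, Xenacoelomorpha: "
            f"{r['vertebrate_present_xenacoelomorpha']}/18 present",
            "",
            "## K296 residue check (packaged synthetic alignment)",
            "",
            f"- calls: {r['residue_counts']}",
            "",
            f"**Mismatches vs published values: {len(self.mismatches)}**",
        ]
        return "\n".join(lines) + "\n"


def reproduce_paper(xenopsin_absent: bool = False) -> ReproductionReport:
    """Run every desk-scale stage on the packaged fixtures.

    ``xenopsin_absent`` additionally controls which scenario the headline
    ``losses`` entry refers to; both scenarios are always computed.
    """
    results: dict = {}
    mismatches: list[dict] = []

    def check(key: str, computed, expected) -> None:
        results[key] = computed
        if computed != expected:
            mismatches.append({"key": key, "computed": computed, "expected": expected})

    stage = "dollo-reconstruction"
    try:
        trees = fixtures.builtin_trees()
        configs = {name: fixtures.packaged_configs(name) for name in trees}
        main = fixtures.opsin_matrix_main()
        absent = fixtures.opsin_matrix_xenopsin_absent()

        cmp_main = compare_hypotheses(main, trees, configs, UncertainPolicy.AS_PRESENT)
        cmp_absent = compare_hypotheses(absent, trees, configs, UncertainPolicy.AS_ABSENT)
        check(
            "losses_main",
            {n: s.n_losses for n, s in cmp_main.scenarios.items()},
            EXPECTED["losses_main"],
        )
        check(
            "losses_xenopsin_absent",
            {n: s.n_losses for n, s in cmp_absent.scenarios.items()},
            EXPECTED["losses_xenopsin_absent"],
        )
        check(
            "parallel_main",
            {n: len(s.parallel_loss_families()) for n, s in cmp_main.scenarios.items()},
            EXPECTED["parallel_main"],
        )
        check(
            "parallel_xenopsin_absent",
            {n: len(s.parallel_loss_families()) for n, s in cmp_absent.scenarios.items()},
            EXPECTED["parallel_xenopsin_absent"],
        )
        results["winners_main"] = cmp_main.winners
        results["scenario_detail"] = {
            n: s.to_dict()
            for n, s in (cmp_absent if xenopsin_absent else cmp_main).scenarios.items()
        }

        stage = "ancestral-repertoire"
        reps = {
            name: ancestral_repertoire(cmp_main.scenarios[name], trees[name], BILATERIAN_ANCESTOR)
            for name in trees
        }
        check(
            "repertoire_bilateria",
            {n: len(rep) for n, rep in reps.items()},
            EXPECTED["repertoire_bilateria"],
        )
        results["repertoire_families"] = {n: sorted(rep.families) for n, rep in reps.items()}

        check(
            "xenacoelomorpha_opsin_types",
            main.count_present("Xenacoelomorpha"),
            EXPECTED["xenacoelomorpha_opsin_types"],
        )

        stage = "pathway-report"
        table = fixtures.phototransduction_table()
        rep = pathway_report(table.matrix, table.pathway_of)
        fly_xen = rep[("fly", "Xenacoelomorpha")]
        check("fly_absent_xenacoelomorpha", fly_xen.n_absent, EXPECTED["fly_absent_xenacoelomorpha"])
        results["fly_present_xenacoelomorpha"] = fly_xen.n_present
        results["fly_absent_genes_xenacoelomorpha"] = [
            table.gene_names[f] for f in fly_xen.absent
        ]
        check(
            "fly_absent_chordata",
            rep[("fly", "Chordata")].n_absent,
            EXPECTED["fly_absent_chordata"],
        )
        check(
            "vertebrate_present_xenacoelomorpha",
            rep[("vertebrate", "Xenacoelomorpha")].n_present,
            EXPECTED["vertebrate_present_xenacoelomorpha"],
        )

        stage = "residue-check"
        aln, truth = fixtures.packaged_alignment()
        calls = classify_sequences(aln, truth.reference_id, truth.reference_position)
        summary = summarize_calls(calls)
        results["residue_counts"] = summary["counts"]
        check("residue_lysine_absent", summary["counts"][Call.LYSINE_ABSENT.value], 1)
        check("residue_truncated", summary["counts"][Call.UNDETERMINED_TRUNCATED.value], 1)
    except Exception as exc:
        raise RuntimeError(f"reproduction stage {stage!r} failed: {exc}") from exc

    return ReproductionReport(results, mismatches)
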