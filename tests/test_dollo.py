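"""Dollo reconstruction: gain inference, minimal losses, suppression,
repertoires, hypothesis comparison, and equivalence with the exhaustive
single-gain oracle."""

import numpy as np
import pytest

from conftest import random_binary_tree
from opsin_dollo.dollo import (
    ConfigurationError,
    FamilyConfig,
    NoOriginError,
    ancestral_repertoire,
    compare_hypotheses,
    infer_gain_node,
    reconstruct_family,
    reconstruct_scenario,
    replay_family,
)
from opsin_dollo.matrix import PresenceMatrix, State, UncertainPolicy, parse_matrix
from opsin_dollo.simulate import simulate_dollo_matrix
from oracle import exhaustive_min_losses

POLICY_ABSENT = UncertainPolicy.AS_ABSENT


def one_family_matrix(clades, present):
    cells = {
        ("fam", c): State.PRESENT if c in present else State.ABSENT for c in clades
    }
    return PresenceMatrix(["fam"], list(clades), cells)


class TestGainInference:
    def test_gain_is_lca_of_present_terminals(self, nephrozoa, main_matrix):
        # present in Cnidaria and Xenacoelomorpha → eumetazoan (root) origin
        assert infer_gain_node(main_matrix, "anthozoa_I", nephrozoa) == "Eumetazoa"

    def test_single_terminal_family_gains_on_its_own_branch(self, nephrozoa, main_matrix):
        assert infer_gain_node(main_matrix, "xeno_specific", nephrozoa) == "Xenacoelomorpha"

    def test_override_pins_gain_above_lca(self, nephrozoa, main_matrix):
        cfg = FamilyConfig("xeno_specific", gain_override="Bilateria")
        assert infer_gain_node(main_matrix, "xeno_specific", nephrozoa, cfg) == "Bilateria"

    def test_all_absent_family_has_no_origin(self, nephrozoa):
        m = one_family_matrix(nephrozoa.leaves, present=set())
        with pytest.raises(NoOriginError, match="no origin"):
            infer_gain_node(m, "fam", nephrozoa)

    def test_non_ancestral_override_rejected(self, nephrozoa, main_matrix):
        cfg = FamilyConfig("anthozoa_I", gain_override="Deuterostomia")
        with pytest.raises(ConfigurationError, match="not ancestral"):
            infer_gain_node(main_matrix, "anthozoa_I", nephrozoa, cfg)


class TestPerFamilyEvents:
    def test_anthozoa_I_lost_three_times_under_xenambulacraria(
        self, xenambulacraria, main_matrix
    ):
        ev = reconstruct_family(main_matrix, "anthozoa_I", xenambulacraria)
        assert sorted(ev.losses) == ["Ambulacraria", "Chordata", "Protostomia"]

    def test_chaopsin_lost_twice_under_xenambulacraria(self, xenambulacraria, main_matrix):
        ev = reconstruct_family(main_matrix, "chaopsin", xenambulacraria)
        assert sorted(ev.losses) == ["Protostomia", "Xenacoelomorpha"]

    def test_xenopsin_lost_once_in_deuterostomes_under_nephrozoa(
        self, nephrozoa, main_matrix
    ):
        ev = reconstruct_family(main_matrix, "xenopsin", nephrozoa)
        assert ev.losses == ["Deuterostomia"]

    def test_ubiquitous_family_has_no_losses(self, nephrozoa):
        m = one_family_matrix(nephrozoa.leaves, set(nephrozoa.leaves))
        ev = reconstruct_family(m, "fam", nephrozoa)
        assert ev.losses == [] and ev.gain_node == "Eumetazoa"

    def test_losses_listed_in_postorder(self, xenambulacraria, main_matrix):
        ev = reconstruct_family(main_matrix, "anthozoa_I", xenambulacraria)
        order = xenambulacraria.postorder()
        assert ev.losses == sorted(ev.losses, key=order.index)

    def test_surrogate_absences_suppressed_not_counted(self, nephrozoa, main_matrix, configs):
        ev = reconstruct_family(
            main_matrix, "xeno_specific", nephrozoa, configs["nephrozoa"]["xeno_specific"]
        )
        assert ev.losses == []
        assert ev.suppressed == [("Nephrozoa", "r_opsin_canonical")]


class TestScenarios:
    def test_loss_totals_main(self, both_trees, main_matrix, configs):
        for name, expected in (("xenambulacraria", 11), ("nephrozoa", 4)):
            s = reconstruct_scenario(
                main_matrix, both_trees[name], configs[name], tree_name=name
            )
            assert s.n_losses == expected

    def test_loss_totals_xenopsin_absent(self, both_trees, absent_matrix, configs):
        for name, expected in (("xenambulacraria", 10), ("nephrozoa", 5)):
            s = reconstruct_scenario(
                absent_matrix, both_trees[name], configs[name], POLICY_ABSENT, tree_name=name
            )
            assert s.n_losses == expected

    def test_internal_branch_loss_replaces_two_terminal_losses(
        self, xenambulacraria, main_matrix, absent_matrix
    ):
        # scoring xenopsin absent in Xenacoelomorpha merges the Chordata and
        # Ambulacraria losses into one deuterostome-branch loss
        main_ev = reconstruct_family(main_matrix, "xenopsin", xenambulacraria)
        assert sorted(main_ev.losses) == ["Ambulacraria", "Chordata"]
        ev = reconstruct_family(absent_matrix, "xenopsin", xenambulacraria, policy=POLICY_ABSENT)
        assert ev.losses == ["Deuterostomia"]

    def test_replay_reproduces_terminal_states(self, both_trees, main_matrix, configs):
        for name, tree in both_trees.items():
            s = reconstruct_scenario(main_matrix, tree, configs[name], tree_name=name)
            for fam, ev in s.families.items():
                assert replay_family(ev, tree) == main_matrix.terminal_states(fam)

    def test_error_carries_family_id(self, nephrozoa):
        m = one_family_matrix(nephrozoa.leaves, set())
        with pytest.raises(NoOriginError, match="'fam'"):
            reconstruct_scenario(m, nephrozoa)


class TestRepertoire:
    def test_bilaterian_repertoire_sizes(self, both_trees, main_matrix, configs):
        expected = {"nephrozoa": 7, "xenambulacraria": 11}
        for name, tree in both_trees.items():
            s = reconstruct_scenario(main_matrix, tree, configs[name], tree_name=name)
            rep = ancestral_repertoire(s, tree, "Bilateria")
            assert len(rep) == expected[name]

    def test_nephrozoan_novelties_excluded_from_bilaterian_repertoire(
        self, nephrozoa, main_matrix, configs
    ):
        s = reconstruct_scenario(main_matrix, nephrozoa, configs["nephrozoa"])
        rep = ancestral_repertoire(s, nephrozoa, "Bilateria")
        assert {"c_opsin", "go_opsin", "neuropsin", "r_opsin_noncanonical"}.isdisjoint(
            rep.families
        )

    def test_terminal_repertoire_matches_matrix_with_suppression_flagged(
        self, nephrozoa, main_matrix, configs
    ):
        s = reconstruct_scenario(main_matrix, nephrozoa, configs["nephrozoa"])
        rep = ancestral_repertoire(s, nephrozoa, "Protostomia")
        assert rep.families == {
            f for f in main_matrix.families if main_matrix.terminal_states(f)["Protostomia"]
        }
        assert rep.suppressed == {"xeno_specific"}

    def test_unknown_node_rejected(self, nephrozoa, main_matrix, configs):
        s = reconstruct_scenario(main_matrix, nephrozoa, configs["nephrozoa"])
        with pytest.raises(KeyError, match="Lophotrochozoa"):
            ancestral_repertoire(s, nephrozoa, "Lophotrochozoa")


class TestComparison:
    def test_nephrozoa_wins_on_main_matrix(self, both_trees, main_matrix, configs):
        cmp = compare_hypotheses(main_matrix, both_trees, configs)
        assert cmp.winners == ["nephrozoa"]
        assert not cmp.to_dict()["tie"]

    def test_parallel_loss_tally_on_xenopsin_absent_variant(
        self, both_trees, absent_matrix, configs
    ):
        cmp = compare_hypotheses(absent_matrix, both_trees, configs, POLICY_ABSENT)
        tally = {n: len(s.parallel_loss_families()) for n, s in cmp.scenarios.items()}
        assert tally == {"xenambulacraria": 2, "nephrozoa": 1}
        # both hypotheses also have a family lost on two branches when an
        # internal-branch loss is included in the count
        multi = {n: len(s.multi_branch_loss_families()) for n, s in cmp.scenarios.items()}
        assert multi == {"xenambulacraria": 2, "nephrozoa": 2}

    def test_identical_trees_tie(self, nephrozoa, main_matrix, configs):
        cmp = compare_hypotheses(
            main_matrix,
            {"a": nephrozoa, "b": nephrozoa},
            {"a": configs["nephrozoa"], "b": configs["nephrozoa"]},
        )
        assert sorted(cmp.winners) == ["a", "b"]

    def test_leaf_set_mismatch_rejected(self, nephrozoa, main_matrix):
        other = random_binary_tree(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="leaf sets"):
            compare_hypotheses(main_matrix, {"a": nephrozoa, "b": other})


class TestOracleEquivalence:
    def test_engine_equals_exhaustive_minimum_on_random_instances(self):
        """On random trees of ≤7 leaves the engine's loss count must equal
        the exhaustive single-gain minimum (Dollo parsimony is exact)."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 120:
            tree = random_binary_tree(rng, int(rng.integers(2, 8)))
            states = {leaf: bool(rng.random() < 0.5) for leaf in tree.leaves}
            if not any(states.values()):
                continue
            m = one_family_matrix(tree.leaves, {l for l, p in states.items() if p})
            ev = reconstruct_family(m, "fam", tree)
            assert ev.n_losses == exhaustive_min_losses(tree, states), (
                tree.to_newick(),
                states,
            )
            checked += 1

    def test_monotonicity_of_loss_counts(self):
        """Flipping an absent terminal to present increases the loss count
        by at most the number of newly implied absent sister branches
        (those hanging off the path from the old gain to the new one),
        and an all-present family has none."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            tree = random_binary_tree(rng, int(rng.integers(3, 8)))
            present = {l for l in tree.leaves if rng.random() < 0.5}
            absent = [l for l in tree.leaves if l not in present]
            if not present or not absent:
                continue
            new_leaf = absent[0]
            grown = present | {new_leaf}
            base = reconstruct_family(
                one_family_matrix(tree.leaves, present), "fam", tree
            ).n_losses
            flipped = reconstruct_family(
                one_family_matrix(tree.leaves, grown), "fam", tree
            ).n_losses
            old_gain, new_gain = tree.lca(present), tree.lca(grown)
            new_siblings = 0
            for start in (old_gain, new_leaf):
                node = start
                while node != new_gain:
                    parent = tree.parent(node)
                    for sib in tree.children(parent):
                        if sib != node and not tree.subtree_leaves(sib) & grown:
                            new_siblings += 1
                    node = parent
            assert flipped <= base + new_siblings
            full = reconstruct_family(
                one_family_matrix(tree.leaves, set(tree.leaves)), "fam", tree
            )
            assert full.n_losses == 0


class TestParsimonyBound:
    def test_engine_never_exceeds_simulated_truth(self, nephrozoa):
        for seed in range(1, 6):
            matrix, truth = simulate_dollo_matrix(nephrozoa, 50, 0.25, seed)
            s = reconstruct_scenario(matrix, nephrozoa)
            assert s.n_losses <= truth.n_losses
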