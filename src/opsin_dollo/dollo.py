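"""Single-gain (Dollo) reconstruction of gene-family histories.

Each family is assumed to originate exactly once on the species tree (at
the last common ancestor of the clades that retain it, unless external
gene-tree evidence pins the gain elsewhere) and can subsequently only be
lost, never regained.  The minimal set of loss branches explaining the
observed terminal presence/absence pattern is unique under this model:
a loss is placed on every maximal subtree devoid of present terminals.

Two bookkeeping refinements mirror how gene-content arguments are made
in practice:

* **Gain overrides** pin a family's origin above the LCA of its present
  terminals (e.g. a lineage-specific family whose gene-tree position
  argues for an older origin).
* **Surrogate suppression** records that a family's absence in a lineage
  is explained by homology with another family retained there (the
  absence is *explained*, not counted as a loss event).  Suppressed
  branches still render the family absent on replay.

Only loss events enter the parsimony comparison between hypotheses;
gains and duplications are bookkept separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .matrix import PresenceMatrix, UncertainPolicy
from .trees import CladeTree

__all__ = [
    "FamilyConfig",
    "FamilyEvents",
    "EventScenario",
    "HypothesisComparison",
    "NoOriginError",
    "ConfigurationError",
    "infer_gain_node",
    "reconstruct_family",
    "reconstruct_scenario",
    "ancestral_repertoire",
    "RepertoireResult",
    "compare_hypotheses",
]


class NoOriginError(ValueError):
    """Family has no present terminal, so no gain node is inferable."""


class ConfigurationError(ValueError):
    """A family configuration contradicts the data or the tree."""


@dataclass(frozen=True)
class FamilyConfig:
    """Per-family reconstruction settings.

    gain_override
        Internal-node name pinning the gain above the LCA of present
        terminals (must be an ancestor of, or equal to, that LCA).
    surrogate_of
        Another family whose presence in a lineage explains this
        family's absence there by homology; such absences are recorded
        as suppressed losses and excluded from loss totals.
    duplication_parent
        ``(parent_family, node)`` recording that this family arose by
        duplication from ``parent_family`` at ``node``.  Pure
        bookkeeping: it moves the family from the gain tally to the
        duplication tally and never affects loss counting.
    """

    family: str
    gain_override: str | None = None
    surrogate_of: str | None = None
    duplication_parent: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.surrogate_of == self.family:
            raise ConfigurationError(f"{self.family}: surrogate_of must name a distinct family")


@dataclass
class FamilyEvents:
    """Reconstructed history of one family on one tree."""

    family: str
    gain_node: str
    losses: list[str]  # branch = name of the node below the lost edge; postorder
    suppressed: list[tuple[str, str]]  # (branch, surrogate family); postorder
    duplication: tuple[str, str] | None = None  # (parent family, node)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "gain_node": self.gain_node,
            "losses": list(self.losses),
            "suppressed": [list(s) for s in self.suppressed],
            "duplication": list(self.duplication) if self.duplication else None,
        }


@dataclass
class EventScenario:
    """Union of per-family event records on one tree, with totals."""

    tree_name: str
    families: dict[str, FamilyEvents]

    @property
    def n_losses(self) -> int:
        return sum(ev.n_losses for ev in self.families.values())

    @property
    def n_gains(self) -> int:
        return sum(1 for ev in self.families.values() if ev.duplication is None)

    @property
    def n_duplications(self) -> int:
        return sum(1 for ev in self.families.values() if ev.duplication is not None)

    def parallel_loss_families(self) -> list[str]:
        """Families lost independently in two or more terminal clades.

        A single loss on an internal branch removes the family from a
        whole clade in one event; it only counts toward the parallel
        tally when at least two *terminal* branches each carry their own
        loss.  (Families whose loss set merely spans multiple branches,
        internal or terminal, are available via
        :meth:`multi_branch_loss_families`.)
        """
        out = []
        for fam, ev in self.families.items():
            terminal_losses = [b for b in ev.losses if b in self._terminal_set]
            if len(terminal_losses) >= 2:
                out.append(fam)
        return out

    def multi_branch_loss_families(self) -> list[str]:
        return [f for f, ev in self.families.items() if ev.n_losses >= 2]

    # populated by reconstruct_scenario
    _terminal_set: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "tree": self.tree_name,
            "n_losses": self.n_losses,
            "n_gains": self.n_gains,
            "n_duplications": self.n_duplications,
            "parallel_loss_families": self.parallel_loss_families(),
            "families": {f: ev.to_dict() for f, ev in self.families.items()},
        }


def infer_gain_node(
    matrix: PresenceMatrix,
    family: str,
    tree: CladeTree,
    config: FamilyConfig | None = None,
    policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
) -> str:
    """Origin node of a family: the configured override, else the LCA of
    the terminals that retain it."""
    present = matrix.present_clades(family, policy)
    if not present:
        raise NoOriginError(f"{family}: no present terminal, no origin inferable")
    lca = tree.lca(present)
    if config is not None and config.gain_override is not None:
        override = config.gain_override
        if override not in tree:
            raise ConfigurationError(f"{family}: gain_override {override!r} not in tree")
        if not tree.is_ancestor_or_equal(override, lca):
            raise ConfigurationError(
                f"{family}: gain_override {override!r} is not ancestral to the "
                f"LCA of present terminals ({lca!r})"
            )
        return override
    return lca


def reconstruct_family(
    matrix: PresenceMatrix,
    family: str,
    tree: CladeTree,
    config: FamilyConfig | None = None,
    policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
) -> FamilyEvents:
    """Minimal Dollo loss set for one family.

    A loss is placed on the branch above every node whose subtree holds
    no present terminal while its parent's subtree does; this is the
    unique minimal cover of the absences given the gain node.  Losses
    whose entire subtree retains the configured surrogate family are
    recorded as suppressed instead of counted.
    """
    _check_leaves(matrix, tree)
    states = matrix.terminal_states(family, policy)
    present = frozenset(c for c, p in states.items() if p)
    gain = infer_gain_node(matrix, family, tree, config, policy)

    losses: list[str] = []
    for node in tree.postorder(gain):
        if node == gain:
            continue
        parent = tree.parent(node)
        sub = tree.subtree_leaves(node)
        if sub & present:
            continue
        if tree.subtree_leaves(parent) & present or parent == gain:
            losses.append(node)

    counted: list[str] = []
    suppressed: list[tuple[str, str]] = []
    surrogate = config.surrogate_of if config else None
    if surrogate is not None:
        surrogate_present = frozenset(matrix.present_clades(surrogate, policy))
    for branch in losses:
        if surrogate is not None and tree.subtree_leaves(branch) <= surrogate_present:
            suppressed.append((branch, surrogate))
        else:
            counted.append(branch)

    duplication = None
    if config is not None and config.duplication_parent is not None:
        parent_family, node = config.duplication_parent
        if node not in tree:
            raise ConfigurationError(
                f"{family}: duplication node {node!r} not in tree {tree!r}"
            )
        duplication = (parent_family, node)

    return FamilyEvents(family, gain, counted, suppressed, duplication)


def replay_family(events: FamilyEvents, tree: CladeTree) -> dict[str, bool]:
    """Terminal states implied by a family's events (losses irreversible).

    Suppressed branches render the family absent exactly like counted
    losses; the distinction matters only for the event totals.
    """
    lost_below = {b for b in events.losses} | {b for b, _ in events.suppressed}
    states: dict[str, bool] = {}
    gained = tree.subtree_leaves(events.gain_node)
    for leaf in tree.leaves:
        if leaf not in gained:
            states[leaf] = False
            continue
        path = tree.path_to_root(leaf)
        # nodes strictly below the gain node, leaf-first
        below = path[: path.index(events.gain_node)] if events.gain_node in path else path
        states[leaf] = not any(n in lost_below for n in below) and leaf in gained
    return states


def reconstruct_scenario(
    matrix: PresenceMatrix,
    tree: CladeTree,
    configs: Mapping[str, FamilyConfig] | None = None,
    policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
    tree_name: str = "tree",
) -> EventScenario:
    """Reconstruct every family in the matrix on one tree."""
    configs = configs or {}
    records: dict[str, FamilyEvents] = {}
    for family in matrix.families:
        try:
            records[family] = reconstruct_family(
                matrix, family, tree, configs.get(family), policy
            )
        except (NoOriginError, ConfigurationError) as exc:
            raise type(exc)(f"family {family!r}: {exc}") from None
    scenario = EventScenario(tree_name, records)
    scenario._terminal_set = frozenset(tree.leaves)
    return scenario


@dataclass
class RepertoireResult:
    """Gene families inferred at an internal node.

    ``families`` are present under the scenario; ``suppressed`` are
    families absent on the path only through surrogate-explained events
    (flagged separately so repertoire counts remain reproducible without
    conflating homology bookkeeping with loss)."""

    node: str
    families: set[str]
    suppressed: set[str]

    def __len__(self) -> int:
        return len(self.families)


def ancestral_repertoire(
    scenario: EventScenario, tree: CladeTree, node: str
) -> RepertoireResult:
    """Families present at ``node``: gained at-or-above it with no loss
    on the root-to-node path."""
    if node not in tree:
        raise KeyError(f"unknown node {node!r}")
    path = set(tree.path_to_root(node))
    families: set[str] = set()
    suppressed: set[str] = set()
    for fam, ev in scenario.families.items():
        if not tree.is_ancestor_or_equal(ev.gain_node, node):
            continue
        lost_on_path = any(b in path for b in ev.losses)
        suppressed_on_path = any(b in path for b, _ in ev.suppressed)
        if lost_on_path:
            continue
        if suppressed_on_path:
            suppressed.add(fam)
        else:
            families.add(fam)
    return RepertoireResult(node, families, suppressed)


@dataclass
class HypothesisComparison:
    """Loss/gain/duplication table over candidate species trees."""

    scenarios: dict[str, EventScenario]

    @property
    def winners(self) -> list[str]:
        """Hypotheses with the minimal loss count (ties all reported)."""
        best = min(s.n_losses for s in self.scenarios.values())
        return [name for name, s in self.scenarios.items() if s.n_losses == best]

    def table(self) -> list[dict]:
        return [
            {
                "hypothesis": name,
                "n_losses": s.n_losses,
                "n_gains": s.n_gains,
                "n_duplications": s.n_duplications,
                "parallel_losses": len(s.parallel_loss_families()),
                "parallel_loss_families": s.parallel_loss_families(),
                "multi_branch_loss_families": s.multi_branch_loss_families(),
            }
            for name, s in self.scenarios.items()
        ]

    def to_dict(self) -> dict:
        return {
            "table": self.table(),
            "winners": self.winners,
            "tie": len(self.winners) > 1,
        }


def compare_hypotheses(
    matrix: PresenceMatrix,
    trees: Mapping[str, CladeTree],
    configs: Mapping[str, FamilyConfig]
    | Mapping[str, Mapping[str, FamilyConfig]]
    | None = None,
    policy: UncertainPolicy = UncertainPolicy.AS_PRESENT,
) -> HypothesisComparison:
    """Reconstruct the matrix on each candidate tree and rank by losses.

    ``configs`` may be a single family→config mapping applied to every
    tree, or a tree-name→(family→config) mapping when bookkeeping (e.g.
    duplication nodes) differs between hypotheses.
    """
    if len(trees) < 2:
        raise ValueError("need at least two trees to compare")
    leaf_sets = {name: frozenset(t.leaves) for name, t in trees.items()}
    if len(set(leaf_sets.values())) != 1:
        raise ValueError(f"trees have different leaf sets: {leaf_sets}")

    def configs_for(name: str) -> Mapping[str, FamilyConfig] | None:
        if configs is None:
            return None
        sample = next(iter(configs.values()), None)
        if isinstance(sample, FamilyConfig):
            return configs  # type: ignore[return-value]
        return configs.get(name)  # type: ignore[union-attr]

    scenarios = {
        name: reconstruct_scenario(matrix, tree, configs_for(name), policy, tree_name=name)
        for name, tree in trees.items()
    }
    return HypothesisComparison(scenarios)


def _check_leaves(matrix: PresenceMatrix, tree: CladeTree) -> None:
    m, t = set(matrix.clades), set(tree.leaves)
    if m != t:
        raise ValueError(f"matrix clades {sorted(m)} do not match tree leaves {sorted(t)}")
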