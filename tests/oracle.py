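"""Exhaustive single-gain oracle, independent of the reconstruction engine.

Enumerates every assignment of presence states to internal nodes under
every admissible gain node (exactly one absent→present transition, no
regain below a loss) and returns the minimal number of loss edges
consistent with the observed leaf states.  Exponential in tree size; for
trees of ≤7 leaves this is at most a few hundred assignments.
"""

from __future__ import annotations

from itertools import product

from opsin_dollo.trees import CladeTree


def exhaustive_min_losses(tree: CladeTree, leaf_states: dict[str, bool]) -> int:
    present = {leaf for leaf, p in leaf_states.items() if p}
    if not present:
        raise ValueError("no present leaf; no single-gain history exists")
    best: int | None = None
    for gain in tree.postorder():
        if not present <= tree.subtree_leaves(gain):
            continue
        under = tree.postorder(gain)
        internals = [n for n in under if not tree.is_leaf(n) and n != gain]
        for bits in product((True, False), repeat=len(internals)):
            state = {n: b for n, b in zip(internals, bits)}
            state[gain] = True
            for leaf in tree.subtree_leaves(gain):
                state[leaf] = leaf_states[leaf]
            # Dollo consistency: absent parent cannot have a present child
            ok = True
            losses = 0
            for n in under:
                if n == gain:
                    continue
                parent_state = state[tree.parent(n)]
                if state[n] and not parent_state:
                    ok = False
                    break
                if parent_state and not state[n]:
                    losses += 1
            if ok and (best is None or losses < best):
                best = losses
    assert best is not None
    return best
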