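"""Compare the two placements of Xenacoelomorpha by Dollo loss count.

Reconstructs every opsin family's gain/loss history on both species-tree
hypotheses and prints the loss totals, the parallel-loss tallies and the
most parsimonious hypothesis.  Fewer losses means the topology explains
the observed family distribution with less convergent gene loss.
"""

from opsin_dollo import compare_hypotheses, fixtures

matrix = fixtures.opsin_matrix_main()
trees = fixtures.builtin_trees()
configs = {name: fixtures.packaged_configs(name) for name in trees}

result = compare_hypotheses(matrix, trees, configs)
for row in result.table():
    print(
        f"{row['hypothesis']:>16}: {row['n_losses']:2d} losses, "
        f"{row['parallel_losses']} families lost in parallel "
        f"({', '.join(row['parallel_loss_families']) or 'none'})"
    )
print(f"most parsimonious: {', '.join(result.winners)}")

# Expected output:
#          nephrozoa:  4 losses, 1 families lost in parallel (chaopsin)
#    xenambulacraria: 11 losses, 3 families lost in parallel (anthozoa_I, chaopsin, xenopsin)
#   most parsimonious: nephrozoa
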