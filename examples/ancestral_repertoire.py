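"""Infer the opsin repertoire of the last common bilaterian ancestor.

Under each hypothesis, a family belongs to the ancestral repertoire if
its gain node lies at or above the Bilateria node and no loss intervenes
on the path from the root.  The two topologies imply repertoires of
different size because moving Xenacoelomorpha moves the node at which
nephrozoan-only families must already have existed.
"""

from opsin_dollo import ancestral_repertoire, fixtures, reconstruct_scenario

matrix = fixtures.opsin_matrix_main()
for name, tree in fixtures.builtin_trees().items():
    scenario = reconstruct_scenario(
        matrix, tree, fixtures.packaged_configs(name), tree_name=name
    )
    rep = ancestral_repertoire(scenario, tree, "Bilateria")
    print(f"{name}: {len(rep)} families at the bilaterian ancestor")
    print("   " + ", ".join(sorted(rep.families)))

# Expected: 7 families under nephrozoa, 11 under xenambulacraria —
# under Nephrozoa the ciliary opsins, Go-opsins, neuropsins and the
# canonical/noncanonical r-opsin split are nephrozoan novelties.
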