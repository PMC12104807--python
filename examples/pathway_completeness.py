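"""Phototransduction pathway completeness per clade.

Reports, for the fly (rhabdomeric) and vertebrate (ciliary) KEGG
reference pathways, how many of the 18 genes each clade retains.  The
near-complete fly pathway and depleted vertebrate pathway in
Xenacoelomorpha is the signature of rhabdomeric phototransduction.
"""

from opsin_dollo import fixtures, pathway_report

table = fixtures.phototransduction_table()
report = pathway_report(table.matrix, table.pathway_of)
for (pathway, group), count in sorted(report.items()):
    absent = ", ".join(table.gene_names[f] for f in count.absent) or "none"
    print(f"{pathway:>10} x {group:<16} {count.n_present:2d}/{count.n_total} (absent: {absent})")

# Expected: fly x Xenacoelomorpha 14/18 (absent: GNBh, Rh1, INAD, ARR2);
# vertebrate x Xenacoelomorpha 5/18 — the ciliary cascade core (CNG
# channels, phosphodiesterase, arrestin) is missing.
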