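# Packaged family configurations for the opsin gain/loss scenarios.
#
# `shared` entries apply under every hypothesis; per-hypothesis blocks add
# bookkeeping that only makes sense on that topology (duplication nodes are
# named after internal nodes of the corresponding tree).
#
# xeno_specific: the xenacoelomorph-specific opsins sit next to the
# r-opsins in the gene tree, so their origin is pinned to the bilaterian
# ancestor and their absence in lineages that retain canonical r-opsins is
# explained by homology (suppressed), not counted as loss.
shared:
  xeno_specific:
    gain_override: Bilateria
    surrogate_of: r_opsin_canonical
nephrozoa:
  r_opsin_noncanonical:
    duplication_parent: [r_opsin_canonical, Nephrozoa]
xenambulacraria: {}
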