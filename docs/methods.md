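# Methods

## The reconstruction model

Each gene family is a binary character on a rooted binary cladogram
over five terminal clades (Cnidaria, Xenacoelomorpha, Protostomia,
Chordata, Ambulacraria).  The model is Dollo parsimony: exactly one
absent→present transition (the gain), any number of present→absent
transitions (losses), no regain.  Under a fixed gain node the minimal
loss set is unique — one loss on the branch above every maximal subtree
devoid of present terminals — so the engine needs no search and no
tie-breaking; event lists are emitted in postorder and the module is
fully deterministic.  The exhaustive enumeration oracle in the test
suite confirms minimality on random trees of up to seven leaves.

Branch lengths are ignored: the comparison between hypotheses is purely
topological, and only loss events are scored.  Gains and duplications
are recorded (duplications via `duplication_parent` bookkeeping) but do
not enter the objective, since the competing hypotheses posit the same
family set and differ only in how many convergent losses they require.

### Gain placement and overrides

By default a family's gain node is the LCA of the terminals that retain
it.  A `gain_override` may pin the origin to any ancestor of that LCA,
for families whose gene-tree position argues for an older origin than
their current distribution shows.  The packaged configuration pins the
xenacoelomorph-specific opsins to the Bilateria node under both
hypotheses: these sequences branch next to the r-opsins, and treating
them as a bilaterian-age lineage is the step-minimising reading of that
placement.  With the override, the Xenambulacraria ancestral repertoire
counts 11 families (the nine classical bilaterian opsins plus
Anthozoa I plus the xenacoelomorph-specific lineage), matching the
published count; without it the family would date only to the
Xenacoelomorpha terminal.

### Surrogate suppression

`surrogate_of` records a homology argument: the absence of family A in a
lineage that retains its surrogate B is "explained", not an independent
loss.  The packaged config marks the xenacoelomorph-specific opsins as
surrogates of the canonical r-opsins, so their absence from Protostomia,
Chordata and Ambulacraria adds zero losses under either hypothesis while
the family still appears (flagged) in replay and repertoire queries.
Suppressed events are logged as first-class records so totals remain
auditable.

### Uncertainty policy

Cells can be `uncertain` — here, the xenopsin/Xenacoelomorpha cell,
supported only by two sequences lacking the K296 lysine (one complete,
one truncated).  The primary analysis resolves uncertain to present; the
alternate scenario resolves it to absent.  The policy is an explicit
argument everywhere, never hard-coded, and the two packaged matrices
differ in exactly that one cell.  Under the absent policy the
Xenambulacraria total drops from 11 to 10 because one loss on the
deuterostome branch replaces the two separate losses in Chordata and
Ambulacraria, while the Nephrozoa total rises from 4 to 5.

### Parallel-loss tally

A family counts as lost in parallel when it carries independent loss
events on two or more *terminal* branches.  A single internal-branch
loss removes the family from a whole clade in one event and is not
parallel in this sense, even when a second loss exists elsewhere; the
raw "lost on more than one branch" count is reported alongside under
`multi_branch_loss_families`.  The terminal definition is the one whose
tallies match the published scenario descriptions across both matrices
(3 vs 1 on the main matrix, 2 vs 1 on the xenopsin-absent variant).

## Matrix granularity

Five terminal clades is the coarsest granularity at which the published
loss enumeration is expressible, and the one used.  Presence at a
terminal means "any sampled descendant lineage retains the family";
within-clade absences (e.g. bathyopsin known only from brachiopods among
protostomes) are below this resolution and deliberately generate no
events.  Consequently families not implicated in any stated loss
(bathyopsin, RGR/retinochrome, the r-opsin lineage retained by
Xenacoelomorpha, the xenacoelomorph-specific opsins) are encoded so
that both hypotheses reconstruct them loss-free.

## Residue-homology classification

The reference coordinate (K296, 1-based and ungapped, after the bovine
rhodopsin numbering) is mapped to an alignment column by counting
non-gap reference characters.  Classification at the column is
mechanical: K → `lysine_present`; any other residue →
`lysine_absent` (ambiguity codes included, with a warning — the
diagnosis demands a positive lysine); a gap → `undetermined_truncated`
when the sequence has no residues at all on one side of the column,
else `undetermined_gap`.  The truncation rule is this package's own
operationalisation of the complete-versus-incomplete distinction; a
human curator might additionally weigh neighbourhood conservation,
which is out of scope.  The embedded default reference is a *synthetic*
348-residue rhodopsin-like sequence with K at position 296 — a
coordinate-faithful stand-in, clearly labelled, not the real bovine
protein.

## Annotation cascade

Hit tables are consumed, never produced; the e-value prefilter defaults
to 1e-5 to match the sensitive-search setting the tables are expected
to come from.  Best-hit reduction ranks by bit score, breaking ties by
lower e-value then lexicographic subject id, and logs every tie it
breaks.  The reciprocal filter keeps a candidate iff at least one of
its top-3 (configurable k) reciprocal hits is a flagged opsin.  Tiered
pathway annotation fires the first applicable tier per protein —
accession match, then exact allow-listed name (never a deny-listed
ambiguous label; no fuzzy matching), then shared cluster id — in a
single non-iterative pass: cluster extension does not chain through
newly annotated proteins.  Clade aggregation is boolean (one annotated
member species marks the whole group, umbrella groups inherit from
subgroups) and idempotent.

## Synthetic data

One integer seed drives a single numpy Generator per generator call; no
global state.  The Dollo simulator draws a uniform gain node, applies
per-branch losses with the given probability (default study condition:
200 families, loss probability 0.2 per branch), discards all-absent
families, and logs every applied event; the truth log replays to the
emitted matrix exactly.  Alignment fixtures plant a lysine column,
substitutions and truncations in otherwise uniform-random sequences —
no substitution matrices or indel models, since identifiability of the
planted truth, not realism, is what the tests need.  Hit fixtures plant
opsin/decoy labels with strictly ordered bit scores (ties only on
request).  Passing tests on these fixtures demonstrate the decision
machinery, not robustness to real transcriptome noise, fragmentary
isoforms, or genuinely ambiguous homology.

## Problem sizes and numerical choices

All headline reconstructions are desk-scale (11 families × 5 clades)
and run in milliseconds.  The oracle-equivalence property is checked on
500 random instances of ≤7 leaves, where exhaustive enumeration is
trivially cheap; the parsimony lower bound on 20 simulation seeds of
200 families.  There is no floating-point numerics anywhere in the
engine — all scores are integer counts — so no tolerances apply;
e-values and bit scores are compared as IEEE doubles with exact
ordering semantics.

## Known limitations

* Probabilistic gene-content models (gain/loss rates, ML or Bayesian
  reconstruction) and full gene-tree/species-tree reconciliation are
  out of scope; the engine deliberately reproduces a parsimony
  argument, not a rate model.
* Per-species matrices are not modelled; the clade granularity above is
  both a design choice and a limit.
* The name tier of the annotation cascade is exactly as good as its
  allow/deny configuration; it performs no string similarity.
* Non-binary trees are refused rather than auto-resolved.
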