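# Methods

## Model and procedure

`pogf` treats a gene list as a sample from a small set of disease-relevant
pathways and measures reproducibility between two such samples at two
levels.  At the *gene* level the directional POG score is the fraction of
one list recovered in the other, `POG12 = m/l1`.  At the *functional* level
the POGF score credits a gene that is absent from the other list but
significantly wired to it in a protein–protein interaction (PPI) network:
`POGF12 = (O + Of12)/l1`, where `O` counts shared genes on the network and
`Of12` counts list-1 genes functionally similar to list 2.

**The PPI-link relation.** Two genes are linked when they interact directly
or share at least one interaction neighbour.  The relation is symmetric, a
superset of the edge relation, and computed over the full network —
including genes in neither list — because functional proximity is a
network-global notion.  For batch scoring the relation is materialized once
as a sparse boolean matrix (`A + A²` with the diagonal cleared).

**Functional similarity.** A gene with `n` link partners among the `N`
other network genes, `k` of which fall in a target list of `M` network
genes, is functionally similar to that list when the upper-tail
hypergeometric probability `P(X >= k)`, `X ~ Hypergeom(N, M, n)`, is
strictly below `alpha` (default 0.05).  The query gene is excluded from its
own target (`M` drops by one) so self-membership never inflates `k`.
`N = |nodes| − 1` — all possible partners of the query — is the only
population under which the hypergeometric model is well defined, and `n`
counts link partners network-wide, not within lists; both choices are
exposed in the returned test records (`k, n, M, N, p`).  A list with no
network member yields `p = 1` rather than an error so batch runs survive
degenerate inputs.

**Chance expectations, normalization, significance.**  `E(POG)` is the mean
POG over `R` random list pairs of the same lengths drawn uniformly without
replacement from a user-supplied background universe (the genome assayed);
`E(POGF)` draws from the network gene set, since functional similarity is
defined only there.  Scores are normalized as `(score − E)/(1 − E)`, a
fixed monotone map, so the permutation p-value of a normalized score equals
that of the raw score by construction.  Permutation p-values count random
scores *strictly larger* than the observed one (ties are not larger); an
exact zero is reported as `< 1/R` in formatted output, and an optional
add-one-smoothed estimator `(b+1)/(R+1)` is available but off by default.
Default `R = 10 000`; the test suite uses 200–2000 where the full count
adds nothing but time.  Each pairwise comparison owns one seeded generator
(spawned per pair in batch runs) and records its seed, so any result line
can be replayed byte-identically.

**Benchmark-anchored selection.**  Candidates are tested for link
enrichment against a benchmark list; Benjamini–Hochberg adjusted values
control the FDR (the standard step-up procedure; selection at a stricter
level is always a subset of selection at a looser one).  Raw `p < alpha`
defines similarity inside POGF, while FDR adjustment is reserved for
selection — the two thresholds serve different error rates and are exposed
separately.

**Pathway-enrichment comparison.**  For a selected/remaining partition the
per-pathway table reports both upper-tail hypergeometric enrichment
p-values and the ratio of pathway fractions
`(|sel ∩ pw|/|sel|) / (|rem ∩ pw|/|rem|)`, rendered `Inf` when only the
selected genes hit the pathway.  The fraction-over-fraction definition is a
design choice: it reproduces the qualitative selected-vs-remaining contrast
and the infinite case exactly, but other ratio conventions exist.  No
multiple-testing correction is applied across pathways; the table reports
raw p-values.

**Representative (non-redundant) subsets.**  Given a list L, a greedy
maximum-coverage loop builds S ⊆ L: each round adds the list gene covering
the most still-uncovered genes (a gene is covered when it is in S or
functionally similar to S), ties broken by higher link-degree, then by
symbol.  Because the similarity test depends on |S|, coverage is
re-evaluated against the current S every round — a gene covered early can
transiently lose coverage as S grows — and an uncoverable gene is
eventually added to S itself, so termination and the contract
`POGF(L→S) = 1` are guaranteed.  Greedy set cover is within a logarithmic
factor of the minimum; provably minimal subsets are out of scope.

## The synthetic generator

`ModularNetworkSpec` defines a planted-partition graph: `n_modules` disjoint
modules of `module_size` genes with independent within-module edge
probability `p_in`, all other pairs (module–module, module–background,
background–background) wired with probability `p_out`.  Defaults — 1000
genes, 10 modules of 40, `p_in = 0.3`, `p_out = 0.005` — give modules about
12 internal neighbours per gene over a background of mean degree 5,
a regime where two disjoint lists drawn from the same modules score
`POG = 0` but `POGF ≈ 0.8`.  `sample_lists` draws list pairs from chosen
module sets with an exact shared-gene count, so overlap and functional
relatedness can be dialed independently.

What the generator emulates: modular functional organization, lists that
sample modules incompletely, and background genes unrelated to any module.
What it does not emulate: the heavy-tailed degree distribution of real PPI
networks, study-specific ascertainment bias, or literature-driven
correlation between list membership and degree.  Passing tests on these
fixtures therefore demonstrate the metric's intended contrast (same-modules
vs disjoint-modules), not calibration on real interactome data.

## Numerical choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf` and match an
  exact rational enumeration oracle to 1e-12 on all populations up to 12.
- Permutation loops replace per-gene tail evaluations by a precomputed
  threshold table `kmin[n]` (smallest significant link count per
  link-degree), which is exact — verified against direct evaluation — and
  orders of magnitude faster.
- Without-replacement sampling uses argpartition over uniform keys, chunked
  to bound memory at a few million doubles.
- Gene symbols are uppercased on input by default (sources disagree on
  case); this is configurable off.  List genes absent from the network are
  excluded from `M` and logged.
- `normalize` returns NaN with a warning when `E = 1` (only possible when
  the lists exhaust the background).

## Known limitations

- **Correlated links inflate the POGF permutation test for
  degree-structured lists.**  The link relation is two-hop, so a single
  background edge from a gene into a foreign module links it to most of
  that module at once; link indicators into a module are therefore strongly
  positively correlated, `k` is overdispersed relative to the hypergeometric
  model, and lists composed entirely of module genes can score above the
  uniform-list permutation null even when drawn from disjoint modules.  On
  the default synthetic spec this produces a nominally significant
  (p < 0.05) cross-module POGF in roughly a quarter of seeds (mean
  cross-module POGF ≈ 0.09 vs null ≈ 0.06).  The same mechanism operates on
  real networks as degree bias: POGF comparisons between lists with very
  different degree profiles should be read against a degree-matched null,
  which the package does not implement.
- The discrete permutation null with strict "larger than" counting makes
  empirical p-values slightly anti-conservative (the fraction below 0.05 is
  ~0.054–0.06 depending on lattice granularity).
- Monte-Carlo expectations carry `O(1/sqrt(R))` error; results record `R`
  and seed so precision can be increased by replay.
- The hypergeometric pathway-enrichment ratio table compares fractions, not
  odds; with very small remaining sets the ratio is unstable.
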