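# Methods

## The network-activity score

The toolkit scores each sample (e.g. a cancer cell line) by how "active" a
protein-interaction network is under that sample's gene-expression profile,
using weighted communicability.

**Edge weighting.** For a connected undirected interactome G = (V, E) and a
strictly positive expression vector x over V, each interaction {i, j} gets

    w_ij = (x_j / Σ_{k∈U_i} x_k) · x_i + (x_i / Σ_{k∈U_j} x_k) · x_j

where U_i is the set of direct interactors of i. The first term is the
expression of i apportioned to j according to j's share of i's neighborhood
expression; the shares over any neighborhood sum exactly to 1 (an identity
the test suite asserts to 1e-12). The formula is symmetric in i ↔ j and
strictly positive on edges.

**Degree normalization.** W is normalized as W'_ij = w_ij / √(d_i d_j) with
d_i = Σ_j w_ij. This corrects for hub nodes with many high-weight edges and
bounds the spectrum of the symmetric matrix W' in [−1, 1]. A consequence
worth knowing: multiplying all of a sample's expression values by a constant
rescales every w_ij by that constant and leaves W' — hence everything
downstream — unchanged. Raw scores are therefore invariant to global
intensity scaling (units, scanner gain), but not to per-gene transforms such
as logging.

**Centrality and score.** Node centrality is the factorially damped
closed-walk count C(i) = (e^{W'})_ii — the subgraph centrality /
self-communicability of node i in the weighted network: walks of length k
contribute with weight 1/k!, so short dense feedback around a node dominates.
Since W' has zero diagonal and eigenvalues in [−1, 1], every C(i) ≥ 1 and the
per-sample score CNA = Σ_i C(i) ≥ |V|. Cohort scores are mapped to (0, 1] by
(x − a + 1)/(b − a + 1) with a, b the cohort minimum and maximum. These
normalized scores are cohort-dependent by construction: recomputing on a
subset of samples changes them. Use raw scores when comparing across cohorts.

**Computation.** W' is symmetric, so the diagonal of e^{W'} is computed
exactly by eigendecomposition, C(i) = Σ_k e^{λ_k} v_ik²: O(n³) per sample,
comfortable to n ≈ 10⁴ nodes. A truncated power series Σ_{k≤K} (W'^k/k!)_ii
(default K = 40; the k = 40 term is bounded by 1/40! ≈ 1e-48 since
‖W'‖₂ ≤ 1) is kept as an independent verification oracle; the two paths
agree to < 1e-9 on random graphs in the acceptance suite.

## Input preparation

*Edge lists* (two-column TSV or SIF) are filtered at parse time:
self-interactions (homodimers), rows with missing/placeholder identifiers,
and duplicate pairs are dropped and counted. Identifiers are opaque strings;
no symbol ↔ Entrez mapping is attempted — mapping tables are user inputs.
Analyses run on the largest connected component (ties broken toward the
component containing the lexicographically smallest label, for determinism).
Filtering happens before component extraction by default.

*Probe-level expression* is collapsed to genes either by keeping the probe
with the largest across-sample standard deviation (population SD, ties by
probe-id order) — the default for building expression matrices — or by
averaging probes per gene, the convention used when correlating individual
transcription-factor expression with drug response.

*Imputation.* Network nodes without a measurement receive the mean over all
measured genes, computed **per sample** (expression is sample-specific; a
matrix-global mean would leak between samples). The imputed count is
reported. Values must be strictly positive because the edge weights divide
by neighborhood sums; zeros are floored at 1e-8 × (global mean) with a
warning, negative values are a hard error.

## Null network model

Degree-preserving randomization uses double-edge swaps
({a,b},{c,d} → {a,d},{c,b}) with rejection of self-loops, multi-edges, and
disconnecting swaps, attempting ⌈10 · |E|⌉ swaps by default (a standard
mixing budget). Connectedness is verified after every accepted swap with an
early-exit BFS checking only that b remains reachable from a: any component
of the post-swap graph must contain one of {a, b, c, d} (walking an old path
from any node, the first removed edge met is ab or cd), and the new edges
a–d and c–b chain all four together once a reaches b, so this single check
suffices. The procedure preserves the degree sequence exactly, keeps the
graph connected and simple, and is reproducible under a seed.

## Association testing

- **Correlation**: Pearson (default) or Spearman between per-sample CNA and
  each drug's normalized IC50, pairwise-complete over missing values,
  minimum 3 shared samples per drug (drugs below that are skipped loudly).
- **Empirical significance**: 1000 permutations of the CNA–sample
  identities; two-sided on |r| with the add-one estimator
  p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), so p ∈ [1/(n_perm+1), 1] and
  is never zero. Calibration under the null is checked by KS uniformity over
  500 replicates in the acceptance suite.
- **Group comparisons** (drug classes, target families, effector pathways):
  two-sided Wilcoxon rank-sum on the coefficient distributions — exact
  enumeration when both groups have ≤ 10 members and no cross-group ties,
  tie-corrected normal approximation otherwise — plus a label-permutation
  empirical p per category pair, reported side by side since either may be
  wanted.
- **Mutation stratification**: correlations recomputed within mutated and
  wild-type sample sets (each ≥ 3 samples); per-drug contrasts via the
  Fisher z-transform (two-sided normal test on z₁ − z₂ with
  SE = √(1/(n₁−3) + 1/(n₂−3))), stratum-level shifts via rank-sum. The
  per-drug flags are the device used to produce candidate drug lists; they
  assume approximate bivariate normality within strata.
- **Tertile deactivation**: nodes are split into low/mid/high tertiles of
  z-standardized centrality (standardization is rank-invariant and purely
  cosmetic; remainders go to the lower tertiles, ties break by node label).
  "Deactivating" a set replaces its members' centralities with the
  component-wide mean centrality of that sample before re-summing, which
  conserves the total exactly when everything is replaced — the natural
  sanity check.
- **Synergy-candidate selection**: partner drugs whose IC50 profile is
  uncorrelated with an anchor drug's within a stratum (two-sided
  t-approximation p ≥ 0.05 for Pearson r).

## Enrichment

One-sided (over-representation) Fisher exact tests on 2×2 tables, p from the
hypergeometric upper tail, odds ratio ad/bc (∞ when bc = 0). Sets covering
< 5 % of the universe (inclusive threshold; optionally relative to the query
via a flag — the universe reading is the default since annotation frequency
filters are conventionally background-relative) are dropped before testing.
Benjamini–Hochberg step-up FDR across the collection (via statsmodels;
verified against a brute-force step-up reference to 1e-12); significance at
q < 0.05. The universe defaults to the main-component node set. The same
engine serves GO terms, pathways, and TF-target collections.

A standalone helper collapses a user-supplied term hierarchy onto one depth
level (default level 4, roots at level 1, depth = shortest root path):
annotations at the target level or deeper are propagated up to their
target-level ancestors, and genes that also occur at level ≤ 3 are excluded.
The enrichment engine itself stays ontology-agnostic.

## Dose-response and synergy

Viability series (fraction unaffected f_u vs dose) are fitted with the
two-parameter median-effect model f_u(x) = 1/(1 + (x/D50)^m) by damped
Gauss–Newton least squares in (log D50, log m) space: initialization at the
dose whose response is nearest 0.5 and m = 1; steps halved up to 20 times on
SSE increase; convergence at step < 1e-10 or SSE improvement below 1e-10
relative; a log-grid search (D50 over the dose range ± 2 log units, m over
[0.1, 10]) plus coordinate polish takes over on divergence, and the
`converged` flag is honest either way. Fits require ≥ 4 points and a
decreasing trend; responses > 1 (plate noise) are clipped to 1 with a
warning. Replicates are averaged before fitting by default.

The combination index of a fixed-ratio design (ratio = drug-2 dose per unit
drug-1 dose, combination fitted on the drug-1-equivalent axis) is, at
fraction-affected level fa,

    CI(fa) = D_c/D₁(fa) + ratio·D_c/D₂(fa),   D_c = combination dose at fa,

with D_i(fa) = D50_i (fa/(1−fa))^{1/m_i} the single-drug effect doses. The
profile is computed over fa = 0.10 … 0.90 in steps of 0.05 and the headline
call uses fa = 0.5: CI ≤ 0.85 synergism, CI ≥ 1.20 antagonism, additive
between. Only the mutually-exclusive (two-term) index is computed; the
cross-term of the mutually-nonexclusive variant is out of scope. A sham
self-combination (a drug at 1:1 with itself) yields CI = 1 at every level —
the identity the test suite checks.

## Synthetic data

The generators produce data with exactly the statistical structure the
analyses assume, so every module is testable offline:

- **Networks**: Barabási–Albert preferential attachment (default, m = 2 →
  heavy-tailed degrees, connected by construction) or G(n, p) with
  largest-component fallback.
- **Expression**: gene latents z_g = √ρ·t + √(1−ρ)·ε_g with a per-sample
  cell-state factor t shared by all genes, exponentiated as
  exp(0.3·z + log 100). Any two genes have latent correlation ρ;
  exponentiation shrinks the Pearson correlation of the positive values to
  (e^{0.09ρ} − 1)/(e^{0.09} − 1) ≈ 0.96·ρ, a calibration fixed once. The
  default ρ = 0.12 matches the co-expression level reported for interacting
  protein pairs in curated interactomes. A global factor was chosen over
  edge-local factors because edge-local sharing gives pair correlations that
  decay with node degree and cannot be tuned to a single target; the cost is
  that non-interacting pairs co-express equally — the generator emulates
  global co-regulation, not network-local co-expression structure, so
  passing tests demonstrate score/statistic correctness, not the empirical
  claim that interacting pairs co-express more than random pairs.
- **Drug response**: IC50 vectors r·z(CNA) + √(1−r²)·noise with
  class-specific target correlation r (defaults: "broad"-acting drugs −0.3,
  "targeted" +0.3, mirroring the sign structure the association analyses
  look for), optional missing-value masking.
- **Combinations**: single drugs follow the median-effect model exactly; a
  fixed-ratio combination at dose pair (d, ratio·d) responds per scaled
  Loewe additivity — the effect level solves d/D₁(fa) + ratio·d/D₂(fa) = α —
  so the true combination index at every level equals α (1 = additive,
  0.5 = synergistic, 1.5 = antagonistic). Loewe is the ground truth because
  the combination index is itself a Loewe-type score; a Bliss oracle would
  not be commensurable. Multiplicative Gaussian viability noise (default
  sd 0.02, replicate means of quadruplicate-style designs supported).

Defaults are desk-scale stand-ins for a cell-line pharmacogenomic screen
(300 nodes, 100 samples, 30 drugs); the acceptance script uses 60–500-node
networks, 100–200 samples, and 50–200 replicate simulations per quantity.

What the generators do **not** emulate: tissue-of-origin structure, mutation
co-occurrence, realistic drug-target annotations, probe-level noise, or
network-local co-expression (above).

## Numerical and degenerate-input conventions

- Empirical p-values always use the add-one estimator and are never 0.
- Constant CNA or IC50 vectors make correlation undefined: the drug is
  skipped with a warning in batch paths and raises in single-drug paths.
- A single-sample cohort normalizes to score 1.0 (a = b degenerate range).
- Tertiles of an all-identical centrality vector are undefined and raise.
- A graph where no valid degree-preserving swap exists (e.g. a triangle) is
  returned unchanged with a warning.
- Raw CNA is reported at 9 significant digits; centralities are float64.

## Known limitations

- Cohort-dependent normalized scores (above) are easy to misuse across
  cohorts; raw scores are the portable quantity.
- The per-drug Fisher-z stratum flags are a pragmatic screening device, not
  a calibrated multiple-testing-controlled discovery procedure.
- Eigendecomposition cost is O(n³) per sample; cohorts over ~2000 nodes ×
  hundreds of samples benefit from precomputing nothing — the weights are
  sample-specific, so each sample pays the full cost.
- The rank-sum exact path requires tie-free small groups; correlation
  coefficients in practice are tie-free, but heavily rounded inputs fall
  back to the asymptotic test.
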