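# Methods

## Model and assumptions

The engine treats miRNA target annotation as a fixed bipartite relation: a
miRNA's target set is whatever the supplied interaction resource records, and
identifiers are opaque, case-sensitive strings (no ID-version harmonization
is attempted — that is a data-preparation concern upstream of the engine).
The enrichment universe is the set of genes annotated in the selected term
collection, i.e. the union of all term gene sets, not the set of genes
appearing in the interaction resource. Annotation-based testing conditions on
what could in principle be reported for a term; target genes outside the
universe are excluded from the urn and counted in the run log. An override to
the intersection of both gene sets is available on the `TermCollection`
consumer side by pre-filtering the GMT.

### Over-representation tests

The classic test is the hypergeometric upper tail, accumulated in exact
integer arithmetic (`math.comb` sums converted through `fractions.Fraction`),
so p-values carry no log-gamma approximation error. This matters at the tail:
downstream Fisher combination takes logs of these values.

The Wallenius variant models unequal sampling weights: in-term genes carry
odds `w` relative to out-of-term genes. It is evaluated by the exact
sequential-draw recursion — the probability vector over the overlap count is
propagated one draw at a time with probabilities proportional to remaining
weights. This recursion *is* the Wallenius distribution (cross-checked in the
tests against `scipy.stats.nchypergeom_wallenius` and against brute-force
enumeration of ordered draws); it is O(n·K) and exact to float rounding for
every urn size this engine meets, so no asymptotic branch is needed.

### Estimating the bias odds

Per-gene targeting propensity is summarized by a nonnegative covariate; the
default is the number of distinct miRNAs interacting with the gene across the
whole resource, the most direct measure of how "visible" a gene is to target
annotation. A monotone probability-weighting function pwf(bias) → P(targeted)
is fit by isotonic regression (direction chosen by correlation) over
equal-count bins — `min(10, universe/20)` bins, at least one — and the term's
odds is the ratio of mean-pwf odds inside versus outside the term, with means
clamped to `[1e-6, 1 − 1e-6]` against degenerate fits. A constant covariate
yields w = 1 and reproduces the classic test to 1e-9 (asserted).

### Combining evidence

Fisher's method is computed directly (−2Σln p against chi-square with 2m df)
rather than through a library call so that two contracts are ours: p = 0
inputs are clamped to the smallest positive float with a warning (upstream
exact tests can return denormal-small values), and the log-sum runs in sorted
order so the combination is permutation-invariant to the last ulp. With one
p-value the method is the identity.

The pathways-union design combines, per term, the p-values of every tested
miRNA by default (`combine_filter="all"`). Combining only the significant
ones inflates significance; that more aggressive reading is available as
`significant_only` (with the number combined reported per row) because both
behaviors have a defensible reading of the workflow, and the choice is
surfaced in the output rather than hidden.

### Rank tests

Mann–Whitney U uses the exact permutation null for tie-free samples with
n ≤ 20 combined, otherwise the normal approximation with tie-corrected
variance and 0.5 continuity correction (both via scipy, behind this module's
orientation convention: `alternative="less"` always means the first sample —
the targeted group — is stochastically smaller). Kolmogorov–Smirnov follows
the same convention, mapping to the ECDF-dominance alternatives, with exact
small-sample p-values when n_x·n_y ≤ 10⁴ without ties.

Pre-ranked CAMERA ranks all genes by the input statistic and compares the
member set's mean rank to the sampling-without-replacement expectation, with
the variance inflated by VIF = 1 + (m − 1)ρ. With ρ = 0 this is the Wilcoxon
normal approximation (asserted against the MWU kernel); the default ρ = 0.01
is the conventional small positive inter-gene correlation for competitive
tests, configurable because no single value suits every screen.

### Context metric

Percent-expressing log2FC: for gene g and context c,
p_gc = 100 · (fraction of c's samples with value ≥ threshold), and the value
is log2((p_gc + ε)/(median over other contexts + ε)). Thresholds are ≥ 1
read for single-cell count matrices and ≥ 10 TPM for tissue sample matrices;
the pseudocount ε = 0.01 percentage points keeps values finite for genes
undetected everywhere (a gene at 0% in all contexts scores exactly 0
everywhere by the symmetry of ε/ε). The metric is deliberately *not*
invariant to rescaling raw values unless the threshold co-scales; a test
documents this.

Context tests are BH-adjusted within each term across contexts — the report
is read one term at a time as a ranking of contexts — with a global
adjustment switch. Groups below `min_group = 3` per side are skipped and
recorded in the report's `skipped` list rather than silently dropped; rank
tests below three observations per side are not meaningful.

### Screen workflow

Element rows are classified gene vs miRNA by a configurable identifier
pattern (default: miRBase-style `hsa-`/`mmu-` prefixes or a `mir` substring).
Only gene rows form the opposite ranking — targets are genes. For the MLE
dialect the signed beta is used directly as the ranking statistic, negated
for the positive direction so that "ascending score = stronger selection"
holds in both directions. The top-k Fisher option has no default k: the
number of top opposite-ranked genes is an experimental-design choice the
caller must state.

## Synthetic fixtures

The generator emulates the statistical structure the workflows consume, not
the scale or metadata of real resources. One planted mechanism threads
through all components:

- interactions: each (miRNA, gene) edge is an independent Bernoulli draw at
  density 0.05, boosted to fold × density (default 4×, capped at 0.95)
  inside the planted-miRNAs × planted-term block;
- terms: 20 random gene sets of 20–50 genes over a 600-gene pool — sizes
  typical of curated pathways; the first term is the planted one;
- expression: negative-binomial counts (dispersion r = 2) for single-cell
  mode or log-normal TPM for tissue mode, 6 contexts × 100 samples, with the
  planted targeted genes repressed by 1 log2 unit in one designated context;
- screen: latent N(0,1) selection scores per direction; planted miRNAs and
  (a fraction 0.8 of) their targets are shifted by −3σ, which concentrates
  them in the top decile of the respective rankings — the mechanism of a
  miRNA knockout de-repressing its targets.

All randomness flows from one seed through fixed per-component child streams
(`default_rng([component_code, seed])`), so adding a component never perturbs
the others and identical spec + seed reproduce byte-identical files.

What passing the planted-recovery tests shows: the engine detects a strong,
cleanly separable mechanism in data with independent edges, homogeneous
background, and no confounding between targeting and expression. Real
interaction resources are correlated (shared 3′-UTR features), real terms
overlap heavily, and real screens carry guide-level noise the gene-level
summary hides — the fixtures make no claim about power in those conditions.
Recovery rates at the canonical 100-seed evaluation are ≈ 95–99% (planted
term first), ≈ 100% (planted context first) and ≈ 90–97% (screen mechanism),
with Monte Carlo noise of a few points across seed sets.

## Numerical choices and degenerate inputs

- Urn invariants (k ≤ min(K, n) ≤ N, w > 0) are validated at construction;
  violations raise, they are not clamped.
- k = 0 gives p = 1 exactly; w → ∞ with n ≥ K drives P(X ≥ K) → 1.
- All-identical rank-test inputs return p = 1 with a warning at the null
  statistic.
- Result ordering ties are broken lexicographically (term_id, mirna_id,
  context_id) for reproducibility.
- TSV output writes floats in shortest round-trip representation, so
  re-reading reproduces every probability bit-for-bit.
- BH adjustment delegates to statsmodels and is asserted elementwise ≥ raw.

## Problem sizes

The test suite and the acceptance script run enumeration oracles at the sizes
where enumeration is exact and fast (all urns N ≤ 30 for the central test,
N ≤ 8 for weighted ordered-draw enumeration, label enumeration for rank tests
at n ≤ 10), calibration on 2,000 replicate null term tests, and recovery on
100 simulated studies at the default fixture scale. These sizes make every
claim checkable by exhaustive computation; the kernels themselves handle
universes of tens of thousands of genes (the Wallenius recursion is the only
super-linear step, O(n·K)).

## Known limitations

- The Wallenius bias covariate is a single scalar per gene; joint correction
  for multiple bias sources (3′-UTR length *and* interaction count) is not
  modeled.
- CAMERA here is the pre-ranked, fixed-ρ variant only; ρ is not estimated
  from expression residuals.
- The screen module analyzes one selection direction per invocation and does
  not descend to sgRNA-level evidence.
- Context tests treat genes as independent observations; co-expression within
  a term makes the effective sample size smaller than the gene count, so
  context p-values are best read as rankings, not calibrated error rates.
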