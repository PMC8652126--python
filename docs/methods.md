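# Methods

## Model and procedure

The pipeline treats GRN inference as per-edge hypothesis testing. An edge
between genes *i* and *k* is supported when their expression profiles remain
associated under four different notions of association, each computed on the
standardized matrix (every gene row centered and scaled to sample sd 1,
denominator n−1):

1. **Correlation** — marginal Pearson correlation. Sensitive to any shared
   variance, including that mediated by third genes.
2. **PCR** — each gene regressed on the leading *k* principal components of
   the other p−1 genes; the component coefficients are back-projected through
   the eigenvector matrix to one coefficient per predictor gene. The
   eigendecomposition is taken per target gene on the leave-one-out predictor
   scatter; components are ordered by descending eigenvalue and each
   eigenvector's sign is fixed so its largest-magnitude entry is positive,
   making results deterministic under the sign ambiguity of eigenvectors.
3. **PLS** — per target, latent components built to maximize covariance with
   the target: unit-norm weights c⁽ˡ⁾ ∝ X⁽ˡ⁾ᵀx_i, scores t⁽ˡ⁾ = X⁽ˡ⁾c⁽ˡ⁾,
   latent coefficient β̂_l = (t⁽ˡ⁾ᵀt⁽ˡ⁾)⁻¹t⁽ˡ⁾ᵀx_i, with the predictor block
   deflated by regressing out t⁽ˡ⁾ after each component (NIPALS). A gene's
   score is the weight-expanded sum Σ_l β̂_l c_k⁽ˡ⁾ — deliberately *not* the
   exact PLS regression coefficient W(PᵀW)⁻¹q, which is a different (also
   defensible) quantity; the weight-expanded form is the one used in the
   network-scoring lineage this package follows.
4. **Ridge** — L2-penalized regression of each gene on all others,
   (X̃ᵀX̃+λI)⁻¹X̃ᵀx_g. With λ=0 this is OLS and, like PCR at k=p−1, reduces
   to unpenalized least squares — a cross-method identity the tests exploit.

Regression scores are directional (the coefficient of k in i's regression ≠
the converse); a single per-pair score is formed by averaging the two
directions. Symmetrization happens per bootstrap replicate, before any
aggregation. Diagonals are held at 0 and never emitted as edges.

**Bootstrap.** The resampling unit is the condition (column), with
replacement, n columns per replicate — the only unit under which edge scores
are statistics of an i.i.d. sample. Rows are re-standardized within each
replicate; without this the correlation bound |S| ≤ 1 can be violated on
resampled columns. All four methods are scored on the *same* replicate
draws, pairing their statistics. A replicate that leaves some gene constant
(possible when a gene has few distinct values) is redrawn, at most 100
times. The correlation t-statistic uses the bootstrap mean s̄ by default;
`cor_t_source="full-data"` substitutes the full-sample correlation, which is
the more conventional plug-in — both are exposed because the choice is
genuinely ambiguous, and they differ only by the small bootstrap bias of s̄.

**Empirical null.** Per method, t-statistics across all p(p−1)/2 edges are
modeled as η₀·N(0,σ₀²) + (1−η₀)·f₁. σ₀ = median(|t|)/Φ⁻¹(0.75) is the
robust half-normal scale: it matches the normal MLE under a pure null but is
driven by the distribution's center, so a minority of strong edges in the
tail barely perturbs it. η₀ = min(1, 2·mean{p > 0.5}) counts mass in the
upper half of the provisional p-value distribution, where the alternative
contributes almost nothing. p-values are two-sided (negative scores mean
repression and are equally interesting); the fdr column is the tail-area
step-up quantity min(1, η₀·p₍ᵣ₎·N/r) with a cumulative-minimum pass, i.e.
Benjamini–Hochberg scaled by η₀. This is a deliberately simple, fully
specified alternative to censored-MLE/Grenander empirical-null machinery:
calibration-equivalent under the null (the test suite checks false-positive
fractions and p-value uniformity) and transparent to test. Fits on fewer
than 50 t-values fall back to σ₀=1, η₀=1 with a warning so toy inputs
behave; all-identical t-values are a hard error.

**Consensus.** Fw = −2Σ ln p_m, computed as a sum of logs with p floored at
1e−300 (floored edges carry a flag column). Under independent uniform nulls
Fw ~ χ²(2m); with the default four methods, 8 df. The four p-values share
one dataset and are positively dependent, so the χ² reference is mildly
anti-conservative — this is why BH adjustment of the combined p-value is the
default gate (α = 0.05), and why the per-edge q_combined is reported
alongside p_combined. With a subset of m ≥ 2 methods the reference is
χ²(2m); a single method is refused since combining one p-value is vacuous.
An optional per-method weight vector generalizes Fw = −2Σ w_m ln p_m; it is
off by default and the unweighted statistic is the one reported.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `B` | 100 | bootstrap replicates; SE estimates have relative error ≈ 1/√(2(B−1)) ≈ 7% |
| `pcr_k` | 3 | principal components retained (1 ≤ k ≤ p−1, k < n) |
| `pls_v` | 3 | PLS latent components (1 ≤ v ≤ min(p−1, n)) |
| `ridge_lambda` | 1.0 | L2 penalty; 0 requires a full-rank design |
| `alpha` | 0.05 | consensus significance level |
| `adjust` | `bh` | BH on p_combined, or `none` for a raw threshold |
| `seed` | 1 | drives all resampling; identical seed ⇒ byte-identical outputs |

k=3, v=3, λ=1.0 mirror the defaults of the R package family these scorers
come from; none are tuned per dataset here.

## Synthetic data

Ground truth is a Gaussian graphical model: planted edges are the non-zero
off-diagonals of a sparse precision matrix Ω, built by placing ±strength at
the chosen pairs, boosting diagonals to the row absolute sum + 0.1
(diagonal dominance ⇒ positive definite), and rescaling to unit diagonal so
off-diagonals are negated partial correlations. A planted edge's realized
|partial correlation| is strength/√((d_i·s+0.1)(d_k·s+0.1)) for node degrees
d — below the nominal strength once a gene has degree ≥ 2. Expression is n
i.i.d. multivariate-normal conditions with covariance Ω⁻¹. This is exactly
the regime in which partial-regression scores (PCR/PLS/ridge) target true
edges, so recovery tests are meaningful; it deliberately omits nonlinear
regulation, temporal dynamics, and count-noise (RNA-seq) marginals, so
passing tests demonstrate correctness of the machinery, not performance on
real transcriptomes. The committed `tests/data/synthetic_expr_8x10.csv`
fixture (8 genes × 10 conditions, 3 planted edges, nominal strength 0.6,
generator seed 7) was produced by this module and serves the I/O and
end-to-end determinism tests.

Study sizes used by the tests and `scripts/acceptance.py` — recovery on 30
genes / 40 edges / n=60 / B=100, calibration on 50 genes / 20 conditions /
B=100, 10,000 Fisher quadruples — are chosen so each study completes in
seconds while leaving Monte-Carlo error well inside the asserted margins.

## Numerical choices

* Standardization uses the sample sd (n−1); constant genes are a named error
  with an opt-in `--drop-constant` filter, since their correlation is
  undefined and silent dropping would change the edge universe.
* File parsing converts cell text with numpy's correctly-rounded
  string→float conversion, so write→read round trips are bit-exact; the
  first offending cell of a malformed file is reported by gene and
  condition id.
* Edge tables are written sorted by descending |score| with lexical
  (gene_a, gene_b) tie-breaks — deterministic across runs.
* Se = 0 with non-zero mean maps t to a signed sentinel (±1e12) rather than
  ±inf, keeping downstream arithmetic finite; |s̄| ≥ 1 in the correlation
  branch is clamped to 1−1e−12. Both paths warn.
* PLS stops early (with a warning) when the deflated block is numerically
  exhausted, capping v at the predictor rank; PCR falls back to a
  least-squares pseudo-solution on rank-deficient component scores.
* CSV/TSV only: delimiter inferred from the file suffix or given explicitly.
  Spreadsheet formats are out of scope; missing values are an error, never
  imputed.

## Limitations

* The χ²(2m) reference ignores inter-method dependence; combined p-values
  are optimistic in absolute terms even though the edge *ranking* (and BH
  control at the reported q) behaves well in the calibration tests.
* The empirical null assumes a unimodal, symmetric t distribution centered
  at 0; heavy contamination (a large fraction of true edges) biases σ₀
  upward and costs power, though η₀ partially compensates in the fdr.
* Scores are linear-association measures; regulatory relationships that are
  nonlinear or condition-specific are invisible to all four scorers, hence
  also to their consensus.
* Bootstrap with small n (< ~15 conditions) is noisy; B = 100 keeps runtime
  modest but SE estimates coarse. Increase B for final analyses.
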