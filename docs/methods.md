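# Methods

## Mixing model and assumptions

`qpdecon` treats a mixed sample's expression vector as a convex
combination of pure-cell-type expectation profiles: `x = S a` with `a` on
the unit simplex. The assumptions this buys and their costs:

- **Linearity on the intensity scale.** Mixing of mRNA is additive in
  linear intensities, not in log space; all deconvolution arithmetic
  therefore runs on linear, untransformed values, and log2 input must be
  declared and is back-transformed first. Scale declaration is explicit
  (`scale="log2"`): no heuristic log detection is attempted, because
  intensity-range heuristics fail silently on filtered or rescaled data.
- **Closure.** Array data are relative, so only mRNA *proportions* are
  identifiable, not absolute cell counts. Systematic per-cell-type
  differences in mRNA yield bias fractions linearly; rank-based
  downstream comparisons are unaffected.
- **A representative basis.** The signature matrix must describe the
  pure populations as they occur in the mixed samples. The robustness
  protocols (below) quantify how much basis error the estimates tolerate.

## The quadratic program

Per sample, the fractions solve
`min ‖S a − x‖² s.t. Σa = 1, a ≥ 0`, a strictly convex QP whenever S has
full column rank. The solver (`qpdecon.qp.solve_simplex_lsq`) is a primal
active-set method specialized to this constraint set:

- Start at the feasible uniform mixture `a = 1/n`. At each step solve the
  equality-constrained KKT system on the currently free coordinates,
  take the longest feasible step (ratio test against `a_i ≥ 0`), and add
  blocking bounds to the working set; at a stationary point, release the
  bound with the most negative Lagrange multiplier or stop when all
  multipliers are non-negative. Finite termination follows from
  convexity; the final iterate solves the KKT system of the true active
  set exactly, so noise-free mixtures are recovered to machine precision.
- The quadratic term is normalized by its largest entry before solving so
  the KKT matrix mixes O(1) blocks with the unit constraint row; step and
  multiplier tolerances (1e-13, 1e-10) are relative to that scale.
- Collinear signature columns make the Hessian singular; a relative ridge
  of 1e-10·mean(diag(SᵀS)) is then added, with a warning.
- Solver round-off in [−1e-9, 0) is clipped to zero and the row
  renormalized; anything more negative raises instead of being masked.
- `qpdecon.qp.kkt_residual` returns the maximum KKT violation of a
  proposed solution and is used in the test suite as an optimality
  certificate, alongside dominance over a brute-force simplex-grid
  search.

Sample solves are independent: nothing is shared across samples, so
results are invariant to sample order and to duplicating columns.

Gene alignment between an expression matrix and a signature is by id
intersection, in the signature's order. At least 50% of signature genes
must be present (an arbitrary but explicit guard; the method degrades
gracefully with missing probes, but silent massive loss should fail
loudly). A basis condition number above 1e6 warns without failing.

## Signature construction

1. **Range filter.** Keep genes whose per-type *mean* expression lies in
   [0.1, 5000] for every type — intensities outside the array's linear
   response range would distort the basis. The filter applies to
   replicate means because means are what enter the basis.
2. **Moderated t.** For every unordered pair of types, a two-group test
   on the log2 scale with empirical-Bayes variance shrinkage: per-gene
   pooled variances s²_g (d_g df) are modeled as scaled-F draws around a
   prior (d₀, s₀²) estimated by moment-matching on log s²_g (digamma /
   trigamma identities; the trigamma inverse by Newton iteration to 1e-14
   relative). The posterior variance
   s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) replaces s²_g in the t statistic,
   which has d₀ + d_g df. Degenerate regimes: an underdispersed variance
   distribution yields d₀ = ∞ with s₀² = mean(s²) (all variances shrunk
   to the common mean — the shrinkage no-op); a group with a single
   replicate falls back to the ordinary pooled t with a warning; fewer
   than two replicates in both groups is an error.
3. **FDR and ranking.** Benjamini–Hochberg control *within each
   contrast* (the pooled-across-contrasts alternative is defensible; the
   per-contrast choice keeps each pair's test family self-contained).
   Genes significant at FDR < 1e-5 in at least one contrast are ranked by
   their maximum |t| over all contrasts, descending, ties broken by gene
   id for determinism.
4. **Size selection.** For each candidate size m (default grid 40…1000
   step 20, clipped to the ranking length), the basis of the top-m genes
   is scored by its 2-norm condition number. The chosen size is the
   *first* local minimum along the grid — the smallest well-conditioned
   basis — falling back to the global minimum when the trace is monotone.
   When design fractions and the corresponding mixture matrix are
   supplied, the per-size deconvolution RMSD is recorded alongside; on
   synthetic systems the two traces correlate positively (Spearman),
   which is the empirical justification for using κ as the selection
   criterion when truth is unavailable.

Testing runs on log2 values (variances are closer to homoscedastic
there); the basis itself stores linear-scale replicate means, since the
mixing model lives on the linear scale.

## Evaluation and robustness protocols

Accuracy metrics are the pooled Pearson correlation (all sample × type
cells) and the RMSD against known fractions; per-type correlations are
also available. Paired group comparisons use the Wilcoxon signed-rank
test (exact null distribution up to n = 25 when |differences| are
tie-free, otherwise the normal approximation with continuity correction;
zero differences dropped); an unpaired rank-sum variant is provided.

Three protocols stress the signature:

- **Random subsets**: rebuild the basis from random draws (sizes 100 and
  200 by default) of the differentially expressed pool, 100 replicates.
- **Size sweep**: top-m bases for increasing m (deterministic).
- **Fold-change distortion**: distort ⌈pct·n⌉ basis genes by a factor f
  or 1/f (equal probability, f = 2 or 5), 100 replicates, recording both
  recovery correlation and the distorted basis' condition number. The
  distortion multiplies the *whole basis row*, i.e. is a gene-level
  distortion affecting every type equally. Draws are coupled across
  percentages: each replicate fixes one random gene order and fold
  sequence and every percentage distorts a prefix, so a larger
  percentage is a strict superset of a smaller one and the distortion
  effect is not confounded by resampling noise.

On the clean synthetic bases built here, fold-change distortion degrades
conditioning *in expectation* — the mean condition number rises with the
distorted percentage — but the per-percentage *median* barely moves: most
draws leave κ near baseline while a tail inflates it. The conditioning
test in the suite therefore compares means at well-separated percentages
(5% vs 30%). Correlation medians are robust and are reported as medians.

## Synthetic data generator

The generator emulates controlled mixing experiments: a handful of pure
types in replicate, block-disjoint marker genes, and mixtures at designed
fractions.

- Baseline intensity per gene: `2^Normal(6, 1)` (≈ 8–512, a plausible
  post-normalization intensity range). Markers of each type (50 per type
  by default, 2000 genes total) are `2^3 = 8`-fold higher in their own
  type. Replicate noise is Normal(0, 0.15) on log2. These defaults are
  chosen so that with 3 replicates per type the FDR < 1e-5 filter
  retains approximately the planted marker set and little else.
- Mixture noise is multiplicative log-normal with unit mean and a given
  coefficient of variation (intensities are positive and
  heteroscedastic); CV = 0.01 corresponds to a 100:1 signal-to-noise
  regime. An additive-Gaussian option (sd = CV · mean signal) exists for
  oracle-equivalence checks.
- Built-in designs: `blood_breast` (15 samples at 0/33/67/100% with
  3/6/3/3 replicates), `liver_kidney` (100/75/25/0% in triplicate), and
  `ten_type_rare` (ten 10-type mixtures, each holding one type at 5%).
- The generator's mixing step is an independent implementation of the
  linear model; the solver never reuses it.

What the generator does **not** emulate: probe-level artifacts, batch
effects, cross-hybridization, correlated marker blocks spanning types,
per-type mRNA-yield differences, or count noise. Passing tests therefore
demonstrate correctness of the estimator under its own model plus
moderate measurement noise — not performance on real arrays, where
basis-representativeness (not solver accuracy) is the binding constraint.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to finish in
seconds while keeping every system overdetermined: 1500–2000 genes,
2–10 types, 3 replicates per type, 10–15 mixtures, 100 replicates per
robustness protocol, and a 0.001-step simplex grid (≈ 5·10⁵ points) as
the brute-force oracle for 3-type instances.

## Known limitations

- Fractions are mRNA proportions, not cell proportions; converting
  between the two needs per-type mRNA yields.
- The signature-size rule (first local κ minimum) is a heuristic; on very
  smooth traces the first local minimum can be an early noise dip. The
  full trace is always returned so the choice can be audited.
- With near-collinear signatures (closely related subtypes) individual
  fractions become unstable even though their sums remain well
  determined; aggregation to major types is the recommended remedy.
- The moderated-t prior fit assumes a common residual df across genes
  (balanced replication); unbalanced designs are handled per contrast
  but share no information across contrasts.
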