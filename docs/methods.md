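# Methods

## The dose–response model

Responses are strictly positive quantities (dry-weight biomass, fatty-acid
concentrations) whose replicate scatter grows with the mean, so the
observation model is a Gamma distribution with constant coefficient of
variation. The mean curve is

    g(E[y]) = α + s(x)

with the log link by default: the additive structure then acts
multiplicatively on the response scale and the fitted mean is positive
everywhere, which the downstream trait integrals require. The inverse link
(the canonical Gamma link) is available behind the same interface; on
these data both links give trait values within the reporting precision,
and the choice is recorded in every report.

The smooth `s` is a low-rank penalized regression spline. Two
constructions are provided:

- **thin-plate (default)** — the eigen-approximation to the full
  thin-plate spline on the unique dosages: radial basis
  η(r) = |r|³⁄12 evaluated between unique doses, eigendecomposed, truncated
  to the leading `k + 1` eigenvectors, with the polynomial-orthogonality
  constraint absorbed by a QR step so the design columns are
  `[1, x, wiggly…]` and the penalty null space is exactly the straight
  lines;
- **cubic** — a natural cubic spline through `k + 1` knots at quantiles of
  the unique doses, in the cardinal (value-at-knot) parameterization, with
  the exact integrated-squared-second-derivative penalty in the
  Green & Silverman band-matrix form.

`k` counts the free basis functions of the centered smooth and defaults
to 4 — deliberately small for 7-point dose grids, and meant to be kept
below five when reproducing the study results (the constructor enforces
this unless `paper_mode=False`).

## Fitting and smoothing-parameter selection

The penalized deviance is minimized by penalized IRLS. For the Gamma/log
combination the working weights are constant, so each iteration is one
penalized weighted least-squares solve (Cholesky); convergence is declared
at a relative deviance change below 1e-10. The effective degrees of
freedom are edf = tr[(XᵀWX + λS)⁻¹XᵀWX].

λ minimizes GCV(λ) = n·D(λ)/(n − γ·edf(λ))² with γ = 1.4, the
df-inflation that guards against undersmoothing when n is small. The
penalty matrix is normalized to unit infinity-norm, so a fixed λ grid —
log-spaced 1e-6…1e4, 101 points — always brackets the transition from the
near-unpenalized fit (edf ≈ k+1) to the linear Gamma GLM (edf = 2). The
grid minimum is refined once by golden-section search on log λ; if the
GCV profile is flat to within 1e-6 relative, the largest λ (smoothest
model) wins. Grid-candidates whose γ-inflated model size reaches n are
treated as infeasible. Tests verify the selected λ against a brute-force
scan on a 10× finer grid for every fitted problem.

The dispersion is estimated by Pearson χ²/(n − edf); it affects only the
confidence bands, never the traits. Bands are ±1.96 posterior standard
errors on the link scale (Bayesian covariance (XᵀWX + λS)⁻¹·φ),
back-transformed — hence positive and asymmetric. Prediction outside the
fitted dose range is refused unless explicitly requested.

## Fitting published summary tables

The packaged tables carry triplicate means ± SD, not raw replicates. Two
fitting modes exist:

- **pseudo-replicates (default)** — each (m, s, n=3) row is expanded to
  the deterministic triple (m − s, m, m + s), the unique symmetric
  three-point set with sample mean m and sample SD (ddof = 1) s. The fit
  then sees n = 21 observations, which matters because n enters the GCV
  denominator: this mode reproduces replicate-level fitting faithfully and
  is what the shipped defaults use.
- **means** — fit the 7 means with prior weight 3. Equivalent information
  in the likelihood, but GCV sees n = 7 and selects visibly smoother fits;
  provided for sensitivity analysis.

The control (dose 0) enters every fit as an ordinary observation — the
smooth covers the whole dosage axis including zero.

## Trait extraction

- **p_max**: dense scan of f on a 2001-point grid, then Brent root-finding
  on the analytic f′ (basis derivative + chain rule) in the bracketing
  interval; ties resolve to the smallest dosage, boundary maxima are
  returned flagged (no stationary point exists there).
- **t_max**: the literal reading "least dosage with f(t) ≥ f(0)" is
  degenerate (dose 0 qualifies); what the trait means operationally — and
  what the published values correspond to — is the *largest* dosage beyond
  the peak still at or above the control level. It is computed as the
  down-crossing of f − f(0) after the peak, bisected to 1e-5
  percent-points. If f never drops below f(0), the trait is the domain end
  with a "no tolerance limit" flag; if the curve never exceeds the control
  the trait is undefined and flagged.
- **μ, σ**: composite Simpson quadrature of x·f, (x−μ)²·f and f on
  [0, t_max] (2001 points). A 10⁶-interval Riemann oracle agrees to 1e-6
  relative in the tests.

Trait dosages are reported to 2 decimals (the measurement precision of
the dose grid); JSON reports keep full precision alongside. The trait set
carries its invariants (0 < p_max ≤ t_max ≤ domain end, 0 < μ < t_max,
σ ≤ t_max/2 by the Popoviciu bound) and validates them on construction.
Note μ may exceed p_max for right-skewed curves (sodium acetate does
this); no ordering between them is asserted. Whether p_max is located on
the link or response scale is immaterial — the log link is monotone, so
the maximizers coincide.

## Synthetic data

The generator draws replicate tables from

    m(x) = b · (1 + s·(x/θ)^p · exp(p·(1 − x/θ))),   y ~ Gamma(κ, m(x)/κ)

on the 7-dose study grid {0, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0}. The family
was parameterized so that θ *is* the maximum potential dosage (the
bracketed factor has its only stationary point at x = θ), giving one
analytically known trait. Defaults — b = 9.5, s = 0.7, θ = 0.55, p = 1.5,
3 replicates, 5 % CV — mirror the scale, peak location and noise level of
the biomass tables (the fixture SDs are ~5 % of their means). Noise above
50 % CV is refused as meaningless for triplicate Gamma fits. Every draw
takes an explicit seed; no global random state is used.

What the family does *not* emulate: it never dips below its baseline, so
its true t_max is always the end of the tested range, and it cannot
produce the sharp supra-linear crash seen at the highest acetate and
glycerol dosages. Recovery tests on it therefore exercise p_max and μ
sharply but t_max only weakly; the published-value reproduction tests on
the real tables cover the dipping case.

Parameter recovery at the study design (7 doses × 3 replicates, 5 % CV,
200 seeds) achieves median absolute errors of ~0.04 percent-points for
p_max and <0.01 for μ, shrinking monotonically as replication grows
3 → 10 → 30.

## Validation strategy

- closed-form oracles: uniform/linear-curve moments, sine-bump peak and
  baseline return, the peaked family's stationary point;
- dense-grid oracles: 10⁶-point scans for roots, 10⁶-interval Riemann
  sums for the quadrature, 10× finer grids for GCV selection;
- an independent engine: the same model fitted to the same data in R's
  mgcv agrees with this implementation to ~1e-7 relative in the fitted
  curve (one test runs Rscript end to end);
- published values: all printed trait dosages reproduce within ±0.05
  percent-points and fitted maxima within a few percent under the shipped
  defaults.

## Known limitations

- The original replicate-level observations are unpublished; the
  pseudo-replicate reconstruction is exact in mean and SD but not in
  skewness, which leaves a residual percent-level uncertainty in fitted
  maxima.
- Single smooth in one covariate only: no tensor products, no REML, no
  families beyond Gamma — out of scope by design.
- No uncertainty intervals on the traits themselves (the trait definitions
  are deterministic functionals of the fitted curve); the report carries
  curve-level bands instead.
- With k = 4 the curve can express at most mild multi-modality; genuinely
  multi-peaked responses would need a larger basis (`paper_mode=False`)
  and the smallest-dose tie-break for p_max becomes load-bearing.
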