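# Methods

## Healing distance

A wound's closure is summarized by the healing distance
`d(t) = reference − size(t)`, measured along the minor axis of the wound
(the direction of least curvature of the margin). The reference is the
size at `t = 0`; when a trajectory enlarges before it shrinks — as happens
during strong inflammatory responses — the maximum observed size is the
reference instead. Under the maximum-size rule, `d` at `t = 0` is positive
for inflamed trajectories: the "distance 0 at baseline" property holds
only for monotone closures, and that is by construction of the printed
subtraction rule, which we apply uniformly to all time points rather than
re-indexing time to the maximum. Distances are additionally clipped below
at zero; with the max-reference rule the clip is provably vacuous (the
test suite brute-forces this), so it serves only as an invariant guard on
hand-edited inputs. A fully healed wound is encoded as
`d = reference`, never by pushing a zero area through the ellipse
inversion (which would return the relation intercept `b`, not 0 — the
inversion warns if asked).

Missing visits are simply absent rows; the linear model needs no
imputation.

## Elliptic wound geometry

Natural wounds are photographed as surface areas. Assuming an elliptic
shape that is preserved during healing, the day-1 axes obey a linear
relation `W = aL + b` (fit by OLS of width on length; for the wild-baboon
population the coefficients are a = 0.121, b = 3.963 mm), and with
`S = πLW/4` the width solves `W² − bW − 4aS/π = 0`. For `S > 0` the root
product is `−4aS/π < 0`, so exactly one root is positive and is returned.
A coefficient-swapped arrangement of this quadratic
(`W² − aW − 4bS/π = 0`) circulates in the applied literature; it is
algebraically inconsistent with the substitution that produces the
quadratic, so the consistent form is the default and the swapped form is
available as `form="printed"` purely for sensitivity analysis. Whether the
swapped form is a typesetting artefact in its source or was actually used
cannot be decided from coefficients alone; the package takes no position
and implements both.

Natural-wound trajectories take their first photographed day as `t = 0`:
only the variation of width over time enters the slope, so the calendar
day of injury is not needed. Lengths are mm and areas mm² internally;
readers convert declared `cm`/`cm2` units explicitly and never guess.

## Mixed model

The response is the healing distance of individual `i` in group `g`:

    d_it = β0_g(i) + β1_g(i)·s(t) + u0_i + u1_i·s(t) + ε_it,
    (u0, u1) ~ N(0, G), ε ~ N(0, σ²).

Design choices, with the genuinely open ones called out:

* **Maximal random structure.** Every individual carries a random
  intercept and a random slope; groups with a single individual abort
  with a clear error rather than silently dropping the slope.
* **Group intercepts.** Group-specific slopes are the quantity of
  interest; group-specific intercepts are included by default
  (`group_intercepts=False` fixes a common intercept). Slopes-only and
  intercepts+slopes parameterizations give identical slope contrasts on
  balanced data; the default is the more conservative.
* **Time scaling.** `s(t) = (t − mean)/sd` with the sample SD (ddof = 1,
  the R `scale()` convention) pooled over all records of the fitted
  dataset — not per group, so that slopes stay comparable. The constants
  are stored in the fit and every reported rate is back-transformed to
  mm/day; reported rates are invariant to disabling the scaling.
* **Estimation.** REML with the fixed effects and σ² profiled out,
  leaving the three log-Cholesky parameters of Ψ = G/σ². Each
  individual's contribution is reduced to 2×2/2×p sufficient statistics
  via the Woodbury identity, so one objective evaluation is O(#individuals)
  small-matrix algebra. Optimization is L-BFGS-B from three fixed starting
  points (Ψ ≈ 0.02·I, 0.3·I, I); the best converged start wins and a
  `ConvergenceError` carrying all optimizer diagnostics is raised if none
  converges.
* **Boundary-avoiding penalty.** The objective adds
  `λ·(log|Ψ| − tr Ψ)`, a weakly-informative Wishart-style penalty
  (λ = 0.01 by default, configurable to 0) that repels the optimizer from
  singular covariance fits, in the spirit of the blme covariance prior.
  The log-Cholesky diagonal is bounded below so the Ψ diagonal never
  falls under 1e−8: on degenerate data (no individual heterogeneity) the
  fit succeeds with G at that floor instead of a boundary singularity, and
  the `singular` flag (smallest eigenvalue < 1e−6 × trace) stays false.
  With λ → 0 the fit converges to the unpenalized REML optimum (verified
  to < 1e−4 in the objective on simulated data). σ² is floored at 1e−12
  so noiseless degenerate inputs remain finite.
* **Replicates.** Duplicate readings enter as independent residual draws
  given the individual's random effects (no replicate-level random
  effect); `merge_replicates(mode="average")` is available for
  sensitivity checks. See the limitation below.
* **Contrasts.** Slope equality among named groups is a Wald chi-square
  on the fixed-effect covariance with df = #groups − 1. Wald χ² was chosen
  over a Kenward–Roger-style small-sample F deliberately: it matches the
  (statistic, df) reporting convention of comparative healing-rate
  analyses, at the cost of small-sample liberality (quantified below).
  Exact reproduction of any particular published χ² value is not expected:
  such values depend on the exact covariance prior used in the original
  fits, which published methods typically leave unstated.
* **Age classes.** Human ages are binned by sample quantiles (median /
  tertile / quartile schemes); boundary ties go to the lower class.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* per-individual linear healing, `width(t) = max(0, initial − (rate+u1)t − u0)`,
  with `(u0, u1) ~ N(0, re_cov)`; widths floor at 0 (complete closure);
* two noise layers — biological scatter (resid_sd, default 1 mm) added
  once per time point, and measurement noise (replicate_sd, default
  0.3 mm) added per duplicate reading — so replicate handling is
  testable. The noise magnitudes are package choices exposed in the
  config, not claims about any particular dataset;
* species schedules: first observation at t = 0, then uniform integer
  gaps of 2–3 d (monkeys), 2–7 d (chimpanzees), 1–2 d (rodents), 3–7 d
  (humans; outpatient cadence, a package choice);
* experimental wounds: 40 mm circular full-thickness defects read as
  widths; natural wounds: elongated ellipses under the day-1 relation
  (a = 0.121, b = 3.963), read as areas through the forward model. Once a
  width falls below the intercept `b` the implied length is negative and
  emission stops for that wound;
* an optional multiplicative inflammation bump,
  `size × (1 + peak_fraction·tri(t; peak_day))` with a triangular profile
  peaking at `peak_day`, as a minimal mechanism to exercise the
  max-reference rule (no functional form is claimed for real inflammation);
* study presets: `study` (vervet 6, Sykes' 5, baboon 6, chimpanzee 5,
  human 24, mouse 8, rat 4 individuals; 0.6 mm/day non-human, 0.25 mm/day
  human generating rates), `baboon_wild` (5 individuals, elliptic areas,
  0.613 mm/day, initial width 18 mm — a plausible canine-tooth laceration),
  and `null_two_groups` (calibration: two identical groups of 6, fixed
  2-day schedule giving 8 visits, one reading per visit).

All randomness flows from one integer seed; identical config + seed gives
byte-identical CSVs.

**What the generator does not emulate:** nonlinear early re-epithelialization
dynamics, contraction-vs-re-epithelialization mechanism differences,
wound-site effects, missing-at-random dropout, or measurement error
correlated with wound size. Passing recovery tests therefore demonstrate
that the pipeline is consistent and well calibrated under its own
assumptions — not that those assumptions hold in any particular real
dataset.

## Calibration findings and limitations

* **Replicate correlation.** Duplicate readings of the same photograph
  share that time point's biological deviation, so treating them as
  independent residuals (the `keep` default) understates fixed-effect
  SEs; in null simulations with duplicated readings the nominal 5% Wald
  contrast rejects at ~9%. With one reading per visit — or averaged
  replicates — the test calibrates (~4.7% over 1000 null replicates).
  The `null_two_groups` calibration preset therefore uses one reading per
  visit; analysts of duplicated real data should prefer
  `replicates="average"` when contrast p-values matter.
* **Wald small-sample liberality.** Even with independent residuals the
  Wald χ² ignores variance-component uncertainty; with ≲ 6 individuals
  per group, p-values near the threshold deserve caution.
* **Problem sizes.** Monte-Carlo checks in the test suite and acceptance
  script use 100 study-emulation seeds (rate recovery), 1000 two-group
  null replicates (type-I error), 1000 single-group replicates (interval
  coverage), and 200 replicates (unbiasedness) — sizes at which the
  binomial/MC error of each summary is well below the tolerance being
  asserted.
* **SE magnitudes are design-dependent.** The synthetic emulation has
  denser, cleaner sampling than typical field data, so its standard
  errors are smaller than those of comparable field analyses even when
  the rates match.
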