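# Methods

`altiphen` implements the statistical core of an altitudinal-gradient ovitrap
study of *Aedes albopictus*: how egg-laying phenology and abundance change
with elevation, and where the species' elevation limit (EL) lies. This note
documents the models, their assumptions, the synthetic data the tests run on,
and the numerical choices.

## Gaussian phenology from a count GLM

For each altitudinal band the weekly mean egg count per trap, mEggs_w, is
modelled as a Gaussian function of time via a log-quadratic count GLM:

    log E[mEggs_w] = b0 + b1·DOY + b2·DOY²

with DOY the mid-week day of year (DOY = 7·week − 3). Band enters as a
categorical factor fully interacted with DOY and DOY², i.e. each band gets its
own (b0, b1, b2); under the negative-binomial family one dispersion θ is
shared across bands. Whenever b2 < 0, the coefficients map in closed form to
the phenological metrics

- µ = −b1/(2b2) — peak day of oviposition (days),
- σ = √(−1/(2b2)) — spread of the season (days),
- h = exp(b0 − b1²/(4b2)) — peak weekly mean egg count (eggs/trap/week),
- N = h·σ·√(2π) — seasonal egg-abundance index (area under the curve).

Assumptions: one peak per season; counts conditionally NB (or Poisson) given
the smooth mean; weeks independent. A band whose fitted b2 is ≥ 0 has no
interior peak and is flagged; its metrics are undefined.

**Families and dispersion.** Poisson and negative-binomial (NB2,
Var = m + m²/θ) fits are compared by AICc, with
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and θ counted as a parameter for the NB.
θ is estimated by maximum likelihood, alternating IRLS for the mean
parameters with a bounded 1-D profile-likelihood update of log θ until the
relative change falls below 1e−8 (the glm.nb algorithm). The response is
rounded to the nearest integer before fitting (count families expect integer
responses; the rounding is switchable via `integerize=False`, which leaves the
quasi-likelihood interpretation to the user).

**Uncertainty.** Standard errors of (µ, σ, N, h) use the delta method with
analytic gradients (grad h = h·(1, µ, µ²), grad N = N·(1, µ, µ²+σ²),
grad µ = σ²·(0, 1, 2µ), grad σ = (0, 0, σ³)); tests cross-check them against
numeric gradients. Confidence intervals are parametric-bootstrap percentiles:
10,000 coefficient vectors drawn from MVN(b̂, V̂) per band, each transformed to
the metrics; draws with b2 ≥ 0 are discarded and counted, and more than 50%
discarded aborts as an unstable shape.

**Activity windows.** All windows follow from (µ, σ, h):

- 80EA = round(2·1.2815516·σ): days between the 10th and 90th percentile of
  the fitted season; depends on σ only.
- Observable activity period = round(2σ√(2 ln h)) for h > 1, else 0: days on
  which the curve predicts more than one egg.
- First/last day of egg laying: the integer days where the curve crosses
  `zero_threshold` (default 0.5 — the day the predicted weekly mean first
  rounds up to a whole egg). A strictly positive threshold is required
  because a Gaussian never reaches zero; 0.5 reproduces the published
  onset/end days within ±1 day in all five bands.

**Asymmetry diagnostic.** The Gaussian curve is symmetric, so systematic
asymmetry shows up in the residuals. A penalized cubic B-spline (P-spline,
basis dimension 12, second-difference penalty, smoothing parameter by GCV) is
fitted to the deviance residuals against DOY. Reported edf excludes the
constant, so edf = 1 means the residual smooth is a straight line; the
p-value is a pseudo-F of the smooth against a constant mean,
F = ((RSS₀−RSS)/(edf−1)) / (RSS/(n−edf)) on (edf−1, n−edf) df. Under a
correctly specified symmetric simulation the measured type-I error is ≈ 5%;
under band-aggregated data it is mildly anti-conservative (≈ 6–7%) because
averaging traps changes the mean-variance relationship the GLM assumes — an
inherited property of fitting count families to weekly means.

## Elevation limit from four altitude-abundance models

Each trap contributes one point: its seasonal maximum weekly egg count
(MEggs) and its altitude. Following the design being emulated, **altitude is
the response** and MEggs the predictor, so the EL — the altitude where
oviposition is predicted to vanish — is each model's fitted value at
MEggs = 0 rather than a root-finding problem. Candidates:

- linear: OLS `altitude = a + b·MEggs`;
- segmented: continuous two-piece linear with breakpoint ψ, fitted by
  profiling least squares over observed MEggs values, refined by iterative
  linearization (ψ ← ψ + γ̂/β̂₂) with 10 bootstrap restarts to escape local
  optima; ≥ 4 points required on each side of the breakpoint;
- exponential decay: `altitude = A·e^(−r·MEggs)` by damped Gauss–Newton
  (A initialised at the maximum altitude, r from a log-linear prefit on
  positive altitudes, step halving, plus the exact profile solution in A at
  each iterate); the EL is A itself, with SE from the Gauss–Newton
  covariance;
- spline smooth ("GAM" candidate): penalized cubic B-spline with basis
  dimension 4 and smoothing parameter fixed at 0.1; the basis family (cubic
  B-spline rather than thin plate) is a documented implementation option.

Models are ranked by AICc from the Gaussian residual likelihood with one
consistent convention: k = number of mean parameters + 1 for the error
variance (segmented counts the breakpoint, so k = 5; the smooth uses
edf + 1). Ties break toward fewer parameters. On synthetic decay data
(44 traps, 50 m altitude noise) the decay model wins the comparison in
roughly 95% of replicates.

**Bootstrap band.** Pointwise 95% BCa intervals for the fitted decay curve
and its intercept come from case resampling (default 1000 replicates), with
the bias correction z₀ from the bootstrap distribution and acceleration a
from jackknife skewness. Bootstrap refits use a profiled grid-plus-Brent
search in r (A is linear given r), which is numerically identical to the
Gauss–Newton optimum but much faster; more than 10% failed refits aborts.
Measured coverage of the intercept interval at study-sized data is ≈ 95%.

**Band predictions.** Inverting the decay law, meggs(alt) = ln(A/alt)/r for
0 < alt ≤ A and 0 above A, gives predicted MEggs bounds per 200-m band
(minimum at the upper edge, maximum at the lower edge). The band containing
A has its upper edge replaced by A; a band starting at sea level is clamped
to the prediction at 1 m and flagged, because the law diverges at altitude 0.

## Municipality classification

Municipalities are assigned to altitude bands by mean altitude (left-open
intervals, so a value on an edge joins the band below) and split at the EL;
a mean altitude exactly equal to the EL counts as below it — the
surveillance-inclusive choice, conservative for public health. Summaries are
exact sums and ratios of the input table; records with missing altitude are
flagged, excluded from ratios and counted.

## Synthetic data: what it emulates, what it does not

`SimulationConfig` defaults encode the emulated design: five 200-m bands from
0 to 1000 m asl, two localities per band, three traps per locality, weeks
23–49, per-band peak days (234, 229, 232, 238, 228) and spreads (33.13,
29.24, 24.96, 27.45, 29.71) days, and the decay law A = 1015 m,
r = 0.003 /egg. Counts are NB with θ = 5 — the within-trap dispersion is not
published, and θ = 5 is a realistic overdispersion for weekly ovitrap egg
counts, chosen once. Each trap's peak weekly mean equals the decay-law MEggs
at its altitude (trap altitudes uniform within their band, since only
locality means are published); `peak_meggs` can override the law for
phenology-only experiments. The optional `skew` parameter replaces the
Gaussian mean with a skew-normal-shaped curve (unit-peak-normalised) to give
the asymmetry test a detectable signal.

Trap maxima can be generated two ways: by taking each simulated trap's
maximum weekly count ("survey" mode), or by drawing altitudes and inverting
the decay law exactly, with Gaussian noise (sd in metres) added to the
recorded altitude ("inverse" mode) — the latter matches the error model the
decay regression assumes and is what the coverage simulations use.

Not emulated: spatial autocorrelation between traps, weather covariates,
diapause/overwintering, multi-year dynamics, and any within-locality variance
structure beyond NB dispersion. Passing tests therefore demonstrate that the
estimators recover the generating process under the stated noise model — not
that the model is correct for any particular field dataset.

## Numerical choices and degenerate inputs

- GCV for the P-spline runs over a geometric grid 1e−8…1e10 (181 points)
  after a Demmler–Reinsch diagonalisation; near-tied scores resolve toward
  the smoother fit, so exactly representable data (e.g. a straight line)
  collapse to the maximally smooth solution. RSS is computed from residuals
  directly to avoid cancellation at near-interpolation.
- Knots are equally spaced and extended past the data range (Eilers–Marx), so
  linear trends lie exactly in the penalty null space; evaluation slightly
  outside the data range (the MEggs = 0 intercept) extends the boundary
  polynomial pieces.
- The decay fit declares convergence on relative RSS change < 1e−12 or an
  absolute RSS floor (exact-fit data); non-convergence raises with the last
  iterate in the message. A non-positive fitted A raises.
- Simulation-scale choices: recovery checks use 100 replicates, coverage 200
  datasets × 1000 bootstrap replicates, calibration 200 replicates — sizes at
  which the Monte-Carlo error is comfortably below the tolerances being
  asserted.
- Degenerate inputs: all-zero bands cannot be fitted (≥ 4 distinct non-zero
  weeks required per band); constant counts produce b2 = 0 and are flagged
  as non-Gaussian; σ = 0 or θ ≤ 0 configs are rejected at construction.

## Known limitations

- The published deviance degrees of freedom of the original fits are mutually
  inconsistent with the stated design (27 weeks × 5 bands, 15 mean
  parameters), so the original AICc values are not exactly reproducible; the
  package asserts recovery properties on synthetic data instead.
- First/last day of egg laying depends on the reporting precision of µ; a
  ±1-day discrepancy with printed values is expected at one band.
- The pseudo-F p-value of the asymmetry smooth does not account for the
  GCV selection of the smoothing parameter; it is mildly anti-conservative
  under model misspecification (see above).
- `adj_r2_` is reported only where it is well defined (not for the nonlinear
  decay fit).
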