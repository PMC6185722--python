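# Methods

## Turnover model

Fresh organic matter (FOM) carbon added with a digestate decays by
first-order kinetics on the Biological Active Time (BAT) axis. With
turnover coefficient k (BAT-d⁻¹), synthesis coefficient η ∈ [0, 1] and a
soil-specific factor b (BAT-days per calendar day), the three carbon
fluxes as fractions of the added carbon are

- FOM remaining: `exp(−k·b·t)`
- carbon reproduction (into active SOM): `η·(1 − exp(−k·b·t))`
- cumulative CO₂: `(1 − η)·(1 − exp(−k·b·t))`

which sum to 1 at every t (enforced to 1e−12 in tests). Doubling b is
exactly equivalent to doubling k, so without published per-soil BAT
values the fitted k is an *effective* rate under the convention b = 1;
this affects the unit of k, not any comparison between residues fitted
under the same convention.

Remineralization of the newly formed active SOM within the ≤ 41-day
incubation window is omitted: the fitted k of ~0.3–0.6 BAT-d⁻¹ turns the
FOM over within days, while the active pool turns over orders of
magnitude slower, and the observed emission plateau matches the one-pool
asymptote 1 − η. An optional `active_turnover` rate adds the second pool
in closed form for sensitivity checks; it defaults to 0.

## Incubation preprocessing

Inputs are tidy per-step CO₂ measurements for amended jars and unamended
controls (four replicates each; controls on a sparser grid). Processing:

1. the control replicates are cumulated and averaged; a least-squares
   polynomial (degree 3 by default, configurable) is fitted to the mean
   cumulative control and evaluated on the sample day grid. Fitting the
   *cumulative* rather than the per-day flux matters: differencing the
   fitted cumulative and subtracting per step is algebraically the same
   subtraction, but the polynomial's prediction error then enters each
   curve value once instead of being summed over the 20-day window, where
   it would otherwise grow into the dominant error term. Evaluation is
   refused more than one scheduled interval beyond the observed control
   range;
2. per replicate, control increments are subtracted per time step
   (negative net increments are kept — clipping them would bias the
   cumulative curve upward), the differences cumulated and normalized by
   the added carbon;
3. per timepoint, the curve value is the replicate mean and the total
   variance is the between-jar sample variance (ddof = 1, deliberately
   not divided by the replicate count: a conservative per-observation
   error scale) plus the control-fit prediction variance;
4. only the daily window (day ≤ 20 by default) enters the fit.

## Inverse modeling

(k, η) minimize the unweighted RMSE between observed and modeled
cumulative mineralization, searched by Nelder–Mead in (log k, logit η) so
the constraints k > 0, η ∈ [0, 1] hold by construction. Three
deterministic starts (default (0.3, 0.8) and two perturbations of it);
lowest RMSE wins, ties broken by lower k. Convergence tolerances 1e−10
(objective) and 1e−8 (simplex size); non-convergence is flagged, not
fatal. A flat all-zero curve raises an unidentifiability error.

Uncertainty comes from the Fisher Information Matrix
`FIM = Jᵀ·diag(1/σᵢ²)·J`, with J the central-difference sensitivity
(relative step 1e−5) of the model output at each observation and σᵢ² the
curve's total variance there; the parameter covariance is FIM⁻¹. The
objective is unweighted while the FIM is variance-weighted — an
intentional asymmetry: the point estimate treats observations alike, the
error budget honors the measured variances. A near-singular FIM raises an
error naming the ill-determined parameter direction.

Because k and η are properties of the residue, per-soil estimates are
pooled as arithmetic means; the pooled sd is `sqrt(mean(sd²))/√n`.

Known calibration caveat: the FIM is diagonal in the observations. Two
error components in real (and fully simulated) curves violate that —
per-point variances estimated from 3 degrees of freedom enter as 1/s²
(a biased precision estimate), and the control-fit error is *common* to
every timepoint of a curve. The second component acts like a single
common offset; η, the curve's asymptote, is maximally sensitive to it, so
±1 sd intervals for η undercover substantially when the control is noisy,
while k intervals are mildly conservative. With independent
per-observation noise and known variances the intervals are calibrated
(≈ 70 % empirical coverage at nominal 68 %); both behaviors are measured
in the test suite and reported by the acceptance script.

## Pedotransfer regressions

Each candidate property (DM, DM_org, C_t, NH₄-N, N_org = N_t − NH₄-N,
N_t, C_t/N_t, C_t/N_org, pH) is regressed (OLS, f(x) = mx + n) against
each parameter; R² is the squared Pearson correlation and the p-value a
two-sided t-test on the slope. The top-R² predictor is selected per
parameter (ties broken by a fixed canonical property order). A multiple
regression is offered only if all pairwise correlations among the
candidate predictors stay below 0.4 in absolute value; otherwise it is
refused with the offending correlations reported — with six calibration
points, collinear predictors cannot be separated honestly.

Predictions for new digestates carry the OLS prediction-interval standard
error, are flagged (not rejected) outside the calibration range, and are
clamped to physical bounds (k ≥ 0.01 d⁻¹, η ∈ [0, 1]).

The bundled reference tables carry the published rounded values, and the
regressions are computed from them as printed; coefficients can differ in
the third decimal from values obtained with unrounded laboratory data
(e.g. the η intercept recomputes as 1.014 against a printed 1.016). The
screening R² for three properties (DM, DM_org, C_t/N_t) is not
reproducible from the rounded tables at all; the package recomputes
rather than hard-codes, and asserts only the reproducible rows and the
ranking.

Range coverage of the study panel against a literature reference range is
`(max − min of study values) / (reference width)`, reported in percent.

## Scenario projection

Soil organic matter is carried as active, stabilized and inert pools
(t C ha⁻¹ in a 0.3 m topsoil of bulk density 1.35 g cm⁻³, both
configurable). Each year the digestate dose (nitrogen-capped:
dry matter = dose/N_t, carbon = DM·C_t) enters as a FOM parcel with the
residue's (k, η); parcels, pools and CO₂ evolve as one coupled linear
system solved exactly over the year by matrix exponential, so the annual
carbon balance closes to machine precision (checked to 1e−9). A
daily-substepping discrete integrator of the same fluxes serves as an
independent oracle (agreement within 1 %).

The pool kinetics are a deliberately simple surrogate, not a calibrated
reproduction of any production model: active-pool decay 0.01 BAT-d⁻¹ with
30 % of the decayed carbon passed to the stabilized pool, stabilized →
active return 4e−4 BAT-d⁻¹, 25 BAT-days yr⁻¹ for the dry Central-German
Chernozem site, and an initial pool split of 7 / 47 / 46 % (active /
stabilized / inert) of the 2 % C_org topsoil. These defaults were chosen
once so that the mean-digestate treatment (~1.04 t C ha⁻¹ yr⁻¹ input,
η ≈ 0.85) holds the initial carbon stock near steady state; treatment
*contrasts* — the quantity of interest — are then driven by η and the
carbon dose. Absolute trajectories and the absolute final-C_org spread
are illustrative only (the default configuration yields ≈ 0.29 % w/w
spread across the six reference digestates after 100 years).

Parameter uncertainty propagates by running each treatment with the mean
parameters and with both parameters at mean ± 1 sd; treatments are
compared by one-way ANOVA on the final C_org of the variants plus
pairwise LSD tests at α = 0.05, summarized as a compact letter display.

## Synthetic data

The generator emulates the incubation design: 27 observation days (daily
1–20, then 22, 24, 27, 30, 34, 36, 41), four replicates, separate
controls every 4th day, a polynomial basal-respiration term shared by
amended and control jars, and Gaussian measurement noise (default
σ = 0.005 of added carbon per observation). Noise placement is
configurable: the default puts independent noise on each cumulative
emission reading (each sampling re-measures the accumulated CO₂ — the
independence structure the variance aggregation and the diagonal FIM
assume); the alternative `noise_on="increments"` models trap-exchange
designs where per-step errors accumulate as a random walk in the
cumulative curve. Under the random-walk alternative, curve errors are
strongly autocorrelated and neither the unweighted fit's accuracy nor the
FIM's calibration targets are meaningful — it exists to quantify exactly
that sensitivity.

Digestate panels are drawn uniformly within configurable property ranges
(defaults spanning the study digestates and the literature: pH 7.2–9.3,
C/N_org 5.9–26.4; ammonium as a fraction of total N so organic N stays
positive), with true parameters from the linear pedotransfer relations
plus Gaussian residuals.

What the synthetic data do **not** emulate: jar-to-jar biological
heterogeneity (the study's replicate variances, and hence its reported
parameter sds of ~0.03–0.08 for k, are larger than measurement noise
alone produces), carbonate-derived CO₂ artifacts, and any temperature or
moisture response. Passing recovery tests therefore demonstrate the
correctness of the estimation machinery under the stated error model, not
field-scale accuracy.

## Problem sizes and determinism

The stochastic test and acceptance computations use 200 synthetic
incubations for the recovery study, 8 replicate 30-digestate experiments
for the end-to-end regression recovery, and 100-year scenarios for six
treatments — sizes at which every Monte-Carlo bound asserted has a
comfortable binomial or normal margin. All random draws flow from
explicit seeds; identical configuration and seed reproduce outputs byte
for byte.
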