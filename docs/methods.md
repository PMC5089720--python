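# Methods

`clamptrace` analyzes hyperinsulinemic-euglycemic clamp experiments that use
a primed-continuous [3-3H]glucose tracer with a labeled ("hot") exogenous
glucose infusate, and ships a mechanistic generator of such experiments so
that every stage of the analysis can be tested against known ground truth.
This note records the models, the defaults and their rationale, the
numerical conventions, and what the synthetic data do and do not establish.

## Tracer model

Plasma glucose is treated as a single well-mixed pool of volume `V` (dl/kg)
with pool fraction `p`. With plasma glucose `G` (mg/dl), plasma tracer
activity `G*` (dpm/ml) and specific activity `SA = 100·G*/G` (dpm/mg), the
non-steady-state rate of total glucose appearance is

    Ra_total(t) = [F*(t) − p·V·G(t)·dSA/dt] / SA(t)        (mg/kg/min)

where `F*(t) = F*_pump + GINF(t)·SA_inf` is the total label delivery —
tracer pump plus the label carried by the glucose infusate. Endogenous
glucose production and whole-body disposal follow as

    EGP(t) = Ra_total(t) − GINF(t)
    Rd(t)  = Ra_total(t) − p·V·dG/dt.

Defaults are the conventional single-pool values `p = 0.65`, `V = 2.2`
dl/kg, both configurable. Analyses of the matched simulator (below) set
`p = 1` with the simulator's `V`, which makes the equation exact and
separates pipeline error from model mismatch. Negative EGP values are
reported as computed and flagged, never clipped: clipping would bias the
hepatic suppression estimate, and undersuppression artifacts are
scientifically meaningful.

Units are fixed at dpm, mg/dl, dl/kg and min internally; microcurie inputs
are converted at 2.22×10⁶ dpm/μCi at the I/O boundary (so the printed
2.7 μCi/g infusate label is 5994 dpm/mg).

### The pump-step convention

The glucose infusion is piecewise-constant and recorded, at each sampling
instant, as the rate in effect while the sample was drawn; the operator's
adjustment applies from that instant on. A sampling instant at which the
pump changed therefore carries two rates, and the smoothed derivatives that
enter Steele's equation are two-sided objects. The instantaneous `GINF`
used in `F*` and in `EGP = Ra − GINF` is the mean of the adjacent recorded
rates ("midpoint" convention). For a stepwise infusion this cancels, term
by term, the half-jump the smoothed `dG/dt` and `dSA/dt` inherit at an
adjustment instant; in matched noise-free tests it reduces the flux
recovery error from ~5–13% to under 0.5%. A "left" convention (recorded
rates as-is) is available.

## Optimal-segments smoothing

Sampled every 10–15 min, glucose and tracer series cannot be
differentiated directly. Each analyte is smoothed independently by a
piecewise cubic with continuous value and first derivative (C1 — second
derivatives may jump at knots, unlike a C2 spline), and `SA` and `dSA/dt`
follow from the two fitted curves by the quotient rule.

**Knots** form a nested dyadic sequence: starting from the record's full
span, the widest segment is repeatedly bisected at its time midpoint. For
the protocol's uniform sampling grids these are equal-data-count quantiles;
nesting makes `RSS(k)` non-increasing in `k` by construction, and
time-based placement keeps the fit stable when part of a record is sampled
more finely.

**Segment count** is the smallest `k` that no richer admissible model
improves on significantly, judged by an extra-sum-of-squares F test at
`alpha = 0.05` against every admissible `k' > k` (testing only `k+1` can
stall when the single next knot misses the feature). When the assay SD is
known, a chi-square lack-of-fit test against that SD replaces the F test;
with `sigma = 0` (noise-free data) it correctly saturates at
`max_segments`. `max_segments` defaults to 6 — a `k`-segment fit spends
`2k+2` degrees of freedom, so a ~30-point series stays far from
interpolation; noise-free validation runs use 12.

The fit itself is an ordinary least squares on a truncated-power cubic
basis in scaled time, converted analytically to per-segment polynomial
coefficients (a `scipy` `PPoly`), so evaluation, differentiation and C1
continuity are exact to rounding. Extrapolation outside the fitted range
is refused.

## Sensitivity endpoints

Basal values average the final 30 min before the insulin start; steady
state averages the final 30 min of the clamp. Both windows are half-open,
`(start, end]`. With `ΔRd = Rd_SS − Rd_basal`, `ΔEGP = EGP_basal − EGP_SS`
(suppression-positive, so a healthy liver has positive hepatic
sensitivity) and `ΔIns = Ins_SS − Ins_basal`:

    SI_P = 10⁴·ΔRd  / (ΔIns·Gluc_SS)
    SI_H = 10⁴·ΔEGP / (ΔIns·Gluc_SS)      (dl/kg/min per μU/ml ×10⁴)
    MCR  = insulin_rate / Ins_SS           (raw ratio)

A between-condition reduction of `SI_H` above 100% therefore means the
anesthetized estimate crossed zero — insulin paradoxically *raising*
glucose production. Insulin MCR is stored as the raw infusion-rate over
steady-state-insulin ratio without further unit conversion.

## The synthetic clamp

The generator integrates, per kg (G mg/dl; C* dpm/dl; I, X μU/ml):

    dX/dt   = −p₂·(X − (I − I_b))                 remote insulin action
    EGP     = max(0, EGP_b·(1 − s_H·X))
    Rd      = (k_b + s_P·X)·G,   k_b = EGP_b/G_b
    V·dG/dt = EGP + GINF − Rd
    V·dC*/dt = F*_pump + GINF·SA_inf − Rd·C*/G
    dI/dt   = 1000·insulin_rate/V_I − n_I·I       (V_I in ml/kg)

Basal is a fixed point by construction; the tracer pool starts at
`prime/(V·weight)`. Protocol constants follow the emulated experiment:
25 μCi prime, 0.25 μCi/min pump, 2.7 μCi/g infusate label,
somatostatin-suppressed endogenous insulin (I ≈ 0 at basal), insulin at
0.75–1.0 mU/kg/min (default 1.0) after 120–180 min of tracer equilibration
(default 120), 180 min of clamp, samples every 10–15 min (default 10).

Single-pool glucose kinetics are deliberate: with `p = 1` and matched `V`
the analysis model is exact, so noise-free recovery tests isolate pipeline
correctness; analyzing the same data with `p = 0.65` exposes pool-fraction
mismatch bias instead.

**Physiology defaults** (invented, per-condition): `G_b = 95` mg/dl,
`EGP_b = 2.5` mg/kg/min, `V = 2.2` dl/kg, `p₂ = 0.05`/min, `n_I = 0.1`/min,
`V_I = 150` ml/kg (so steady-state insulin is `1000·rate/(n_I·V_I) ≈ 67`
μU/ml at 1 mU/kg/min — mid-physiological for a low-dose clamp). The four
condition presets scale insulin action: conscious `s_P` of 4.7 (lean) and
4.0 (fat-fed) ×10⁻⁴ per μU/ml; anesthesia roughly halves `s_P` and
collapses `s_H` toward zero (lean) or below it (fat-fed), reproducing the
direction and rough size of the reported anesthesia effect. `V_I` is
declared in ml/kg because that is the unit under which the closed form
`I_SS = 1000·rate/(n_I·V_I)` yields μU/ml.

**Operator emulation.** GINF is adjusted at each update interval (default
10 min, at the sampling instants) by a positional PI law applied in
increment form on the *measured* glucose, `ΔGINF = Kp·Δe + Ki·e` with
`e = G_b − G_meas`, `Kp = 0.15`, `Ki = 0.05` (mg/kg/min per mg/dl), floored
at zero. Gains were calibrated to the protocol contract — glucose within
5% of basal over the final 30 min on all presets with assay noise — while
keeping the operator's response to single noisy readings modest, as a real
operator's would be. The measured value the controller used is the value
stored in the record.

**Noise model**: multiplicative Gaussian noise with CV 2% on glucose
(autoanalyzer) and 5% on insulin (ELISA); additive tracer counting noise
with SD `1.0·√(dpm/ml)` — at typical activities ~1.2%, consistent with
liquid-scintillation counting statistics plus processing variability.
Between-animal dispersion in cohorts is log-normal with CV 15% (default)
on `EGP_b`, `s_P`, `s_H`, `n_I` (sign-preserving), a quarter of that on
`G_b`, and body weight N(28.5, 2²) kg; `dispersion = 0` disables all
between-animal variation. Everything is reproducible from a single seed.

**What the generator does not emulate**: two-compartment glucose kinetics,
tracer recycling and ³H loss, insulin secretion dynamics (somatostatin
removes them by design), hemodynamics or anesthetic pharmacokinetics, and
drift in basal physiology over the 5-hour study. Passing recovery tests on
these data therefore demonstrates correctness of the estimation chain
under the stated model, not robustness to model misspecification — except
where the pool-fraction mismatch mode is used deliberately.

## Statistics

Group endpoints are summarized as mean ± SEM (undefined, not zero, for
n = 1). Comparisons use the two-sided pooled-variance Student t test
(zero-pooled-variance edge cases: p = 1 for equal means, p = 0 otherwise)
and a diet × anesthesia ANOVA with interaction, computed by explicit
model-comparison projections on sum-coded design matrices. Type II sums of
squares are the default — the standard choice for unbalanced factorials
(the emulated cohort is 16/16/16/8) when main effects are the target; Type
III is available. Tukey HSD compares the four cell means using the
one-way residual mean square, which equals the factorial model's residual.
Both tests hold their nominal 5% size within Monte-Carlo tolerance in
2000-replicate null calibrations.

## Numerical choices and limitations

- ODE integration: RK45, `rtol = atol = 1e-9`, integrating cumulative
  throughputs alongside the states; glucose and tracer mass balances then
  close to rounding (≪ 1e-8 relative) because the balance is a linear
  invariant of the Runge-Kutta stages themselves.
- Problem sizes: validation sweeps use 20 animals per condition for
  recovery statistics and 20 cohort replicates for the condition-contrast
  property; these sizes put Monte-Carlo error well below the effect sizes
  being asserted.
- Per-animal hepatic sensitivity is intrinsically noisy: the hepatic
  increment `ΔEGP` (0.2–0.9 mg/kg/min across presets) is comparable to the
  propagated assay noise of a steady-state EGP estimate (~0.3 mg/kg/min),
  and anesthetized true values sit near zero, so per-animal *relative*
  error on `SI_H` is large no matter the estimator — as in real clamp
  studies, where hepatic SI group SEMs approach the means. Group-level
  contrasts (percent reductions, sign flips) are the robust quantities.
- The steady-state window (final 30 min) sits at the record's edge, where
  smoothing-derivative variance is highest; supplying known assay SDs to
  the smoother tightens segment selection but does not remove this.
- `SmoothCurve` refuses extrapolation rather than returning polynomial
  tails.
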