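# Methods

## Scene geometry and kinematics

The modelled apparatus is a mirror-stereoscope rig: a screen at viewing
distance D = 97 cm, refresh 85 Hz, and a stimulus of two vertical lines at
fixed lateral world coordinates ±x_w approaching the observer along the
midline. A line's visual direction from an eye at lateral offset e is
θ = arctan((x_w − e)/z), its screen rendering x_s = e + D(x_w − e)/z, and
its instantaneous angular speed for approach speed v is the exact
derivative

    dθ/dt = (x_w − e)·v / ((x_w − e)² + z²),

converted once to arcmin/s (×180/π×60). "Speed at a timepoint" always means
this instantaneous derivative, never a frame difference; positions are
defined in continuous time and sampled at frame onsets i/85 s, while the
speed step occurs at exactly t = 0.5 s even though that instant falls
between frames. Tabulated speeds are computed on the cyclopean channel
(e = 0).

Two scene constants are not derivable from first principles and are fixed
as defaults (both configurable):

- **Trajectory placement.** Intervals are symmetric about the screen
  plane: start z₀ = D + s/2 and end z₁ = D − s/2 for total travel s. This
  puts the Fast ladder (40 cm/s, 1 s) at 117→77 cm and the Slow ladder at
  107→87 cm. It is the unique placement that reproduces the published
  per-interval speed endpoints (30.1–43.8–69.5 arcmin/s Fast,
  18.0–21.9–27.2 Slow) and the 117 cm start distance.
- **Line half-separation x_w = 3.0 cm** and **ipd 6.5 cm**. The
  half-separation is recovered by inverting the Fast-standard endpoint
  speeds (`recover_geometry` solves a = x v K/(x²+z₀²),
  d = x v K/(x²+z₁²) jointly for z₀ and x; small-x closed form
  (z₀/z₁)² = d/a seeds a Newton refinement). The ipd affects only the
  per-eye channels, not any tabulated quantity.

Under this convention 10 of 13 published speed cells match to ±0.1 arcmin/s
after rounding; the three highest-speed cells (57.6, 121.4, 33.1) deviate
by ≤ 0.2, presumably reflecting a frame-difference convention in the
original stimulus code; the package documents and tolerates ±0.3 there.

## Stimulus design

Each 2IFC interval shows a 250 ms static image, then 1 s of motion; in
variable intervals the speed steps up after 500 ms. Level k of the 7-level
constant-stimuli ladder runs at v_std − (k−1)·Δ then v_std + (k−1)·Δ
(Fast: Δ = 5 cm/s, level 7 = 10→70; Slow: Δ = 2.5, level 7 = 5→35), so
every level covers the same world distance in the same duration. The
stimulus intensity is the proportion speed change at the changepoint,
(c − b)/c, on retinal speeds; because b and c share the same depth at the
changepoint, this equals (v_after − v_before)/v_after for world-speed
stimuli.

**Constant-retinal-speed (Retina) ladder.** The Retina families hold
angular speed piecewise constant. Their standard speed is derived as the
whole-interval mean cyclopean speed of the matching world standard (total
angular displacement ÷ duration: 45.74 arcmin/s Fast, 22.14 Slow), and
level k scales the world ladder's speed ratios onto that mean. This keeps
the standard genuinely constant, conserves retinal displacement across
levels (mirroring the world ladder's distance conservation), and makes the
(c − b)/c ladder identical across families. The stimulus tables of the
original study print slightly different constants (47.6/7.6/87.4 Fast,
22.3/4.6/40.0 Slow) whose averaging convention is not recoverable from any
scheme tried (time average, endpoint mean, per-half means); those printed
values ship as configuration overrides but the derived route is the
default everywhere.

Participant QC follows the study rules: exclusion iff level-7 accuracy
< 80% in at least two conditions; the training gate is ≥ 50/60 correct in
the final training block. Training-stimulus speeds (283.4; 212.6→354.1;
70.9→495.3 arcmin/s) are stored as documented constants only — note they
do not satisfy the sum-conservation of the main ladders and are never
derived.

## Observers and psychometric fitting

A synthetic observer answers each 2IFC trial independently with success
probability

    p(x) = γ + (1 − γ − λ)·Φ((x − α)/σ),   γ = 0.5, λ = 0,

at intensity x = proportion speed change. No sequential effects are
modelled (the task gives no feedback). Fitting maximises the
product-binomial likelihood over (α, log σ) with Nelder–Mead from a
deterministic start (α at the first level whose empirical accuracy crosses
the mid-asymptote, σ at half the level range; tolerances 1e-10/1e-12).
Under the fixed asymptotes the 75% point equals α, so thresholds are the
fitted location. Data that never rise above chance, or sit at ceiling
everywhere, are flagged non-identifiable and yield no threshold rather
than an extrapolated one. The lapse rate may be raised (≤ 0.06) for
sensitivity analyses, in which case the 75% point uses the closed-form
inverse of the scaled CDF.

## Statistics

The planned analysis is three 2×2 within-subject ANOVAs on thresholds
(World vs Retina, World vs World Control, Retina vs Retina Control, each
crossed with Fast/Slow) — three separate models because each comparison
answers a different question; no omnibus 3-way model. Each effect is
tested against its own participant-by-effect interaction. With two-level
factors every effect has df = 1, the decomposition is algebraically a
paired t-test on per-participant contrast scores (F = t²), sphericity is
moot, and partial η² = SS_eff/(SS_eff + SS_err) = F/(F + df_den). The
implementation computes exactly this contrast form; tests verify it to
1e-9 against a brute-force sums-of-squares oracle and against
`pingouin.rm_anova`. Zero error variance yields an infinite F with a
warning rather than an exception.

Between-subject condition CIs are mean ± t(1−(1−level)/2, n−1)·sd/√n;
the level defaults to 0.95 and is configurable.

Bayesian evidence for a paired contrast is the JZS Bayes factor with a
zero-centred Cauchy prior of width 0.5 on the standardised effect size:
BF10 = ∫ f_nct(t; ν, δ√n) dF_Cauchy(δ) / f_t(t; ν), evaluated by adaptive
quadrature in the prior-CDF domain (relative tolerance 1e-8, robust to
arbitrarily narrow priors). This is deliberately an approximation to — not
a reproduction of — a model-averaged Bayesian RM-ANOVA, which is
sampler-specific and out of scope.

## Synthetic cohorts

A cohort mirrors the human study's shape: 9 participants × 8 conditions ×
7 levels × 3 blocks × 10 trials (1680 trials each), block order and
change-interval assignment randomized per seed. Per-participant true
thresholds are drawn from a truncated normal (floor 0.01) around
scenario-defined condition means; the observer's spread is σ = 0.5·α.
Population means sit in the 0.20–0.37 proportion-speed-change band typical
of speed-change discrimination, with between-participant sd 0.08 — desk
realistic values, fully configurable. Scenarios: `null` (all conditions
0.28), `suppression` (controls at 0.7× the 0.30 main-condition mean — the
stereomotion-suppression pattern), `fast-advantage` (a speed effect
confined to the Retina pair with Retina-Control-Fast easiest, driving the
interaction).

What the generator does *not* emulate: learning/fatigue and block-order
effects, lapses (unless enabled), non-stationary criteria, cue-specific
observer mechanisms (no motion-energy or cue-combination front end), and
any correlation structure between conditions within a participant beyond
the shared population mean. Passing pipeline tests therefore demonstrate
that the *machinery* is calibrated and unbiased under the assumed
generative model — not that human thresholds take these values. Published
human test statistics and threshold magnitudes depend on the deposited
human dataset and are intentionally not reproduced; the pipeline instead
recovers the qualitative pattern (null World-vs-Retina difference; lower
control thresholds under suppression) from the matched scenarios.

## Problem sizes and numerical choices

Calibration studies run at sizes chosen for tight Monte-Carlo error at
desk scale: psychometric bias over 500 replicate fits (|bias| < 0.01
required), MLE-vs-grid-oracle comparison on 50 fixtures (grid resolution
0.001), ANOVA type-I rate over 10,000 null 9×2×2 tables (0.05 ± 0.007),
end-to-end scenario checks over 5 full cohorts per scenario. Quadratures:
BF integrals at 1e-8 relative; geometry inversion via Newton root solve on
the 2-equation system; probabilities clipped at 1e-12 in likelihoods.

## Known limitations

- The Retina-ladder averaging convention of the original stimulus code is
  unrecoverable; the derived ladder is self-consistent but its absolute
  speeds differ from the printed constants by ≈ 4% (overrides provided).
- The per-eye channels assume eyes displaced purely laterally and no
  vergence dynamics; disparities are geometric, not fused percepts.
- The JZS paired BF is a single-contrast approximation; model-averaged
  Bayes factors over the four candidate RM-ANOVA models are out of scope.
- No rendering is performed: luminance, anti-aliasing, aperture noise and
  pixel quantisation are outside the model.
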