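# Methods

`petkin` re-implements, as tested open code, a complete small-animal PET
kinetic-modelling analysis: construction of a metabolite-corrected arterial
input function, blood-based compartmental and graphical quantification,
reference-tissue quantification against a pseudo-reference region, and the
cohort-level statistics comparing a transgenic group against wild-type.
Because the underlying animal scan data are not public, a synthetic-data
generator reproduces the study conditions with known ground truth, so every
stage of the pipeline is testable end to end.

## Data model and units

Time is minutes internally; delimited files carry seconds (matching how
frame schedules are reported) and are converted on read. All activity
concentrations — tissue, plasma and whole blood — are expressed in %ID/g,
so distribution volumes and binding potentials are dimensionless. The
default acquisition schedule is the study's 22-frame/60-min re-binning
(6×10 s, 4×30 s, 4×60 s, 1×180 s, 4×300 s, 3×600 s).

Sampled curves interpolate linearly between samples. Before the first
sample a curve is interpolated from (0, 0) — activity is zero at injection —
except parent-fraction curves, which anchor at (0, 1) because all plasma
activity is intact tracer at injection. After the last sample curves are
held constant; the study never evaluates beyond the last sample, so this
extrapolation only guards edge cases and is our choice, not something the
source analysis specifies.

Frame values are treated as time-averages of the underlying concentration
over the frame (the physically correct reading of accumulated counts);
midpoint evaluation is available as a cheaper alternative
(`frame_method="midpoint"`).

## Input function

The measured plasma curve is corrected for radiolabelled metabolites by
multiplying with the parent fraction f(t). Following the study design, the
default correction uses one population-average f(t) per cohort group (the
arithmetic mean of linearly interpolated individual curves on a common
grid); per-individual correction is available. Between the sparse
measurement times (5, 10, 15, 30, 60 min) f is interpolated linearly and
held constant past the last sample. A blood delay, when fitted, shifts
plasma and whole-blood curves identically and evaluates to zero before the
shifted start.

## Compartment models

The measured concentration is modelled as

    C_model(t) = (1 − V_B)·C_tissue(t) + V_B·C_wb(t),

with V_B the fractional cerebral blood volume, fixed at 3.6% in the default
configuration (a literature value), and whole blood — not plasma — filling
the blood-volume term (the common convention; configurable). C_tissue is
the convolution of the metabolite-corrected plasma curve with the model
impulse response: K1·e^(−k2·t) for one tissue compartment, and for two

    h(t) = φ1·e^(−θ1·t) + φ2·e^(−θ2·t),
    θ1,2 = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4)] / 2,

the eigen-decomposition of the free/bound two-compartment system. Because
the input is piecewise linear, the convolution has an exact per-segment
closed form; `petkin.convolve.ExpConvolver` evaluates it to rounding
accuracy, with series-stabilised primitives for small θ·Δt and the
confluent limit h(t) = K1·e^(−θt)·[1 + (k3+k4−θ)t] switched on when
|θ1 − θ2| < 1e−8 min⁻¹. Agreement with a tight-tolerance LSODA integration
of the ODE system is below 1e−9 relative across a parameter grid spanning
the fit bounds (the test asserts 1e−4).

Macro parameters follow the standard identities V_ND = K1/k2,
BP_ND = k3/k4 (defined as 0 when k3 = 0), V_T = V_ND·(1 + BP_ND); the last
identity holds exactly for every fit output by construction.

Fitting is bounded weighted nonlinear least squares (trust-region
reflective), with K1 ∈ [0, 5], k2, k4 ∈ [1e−6, 5], k3 ∈ [0, 5] min⁻¹,
V_B ∈ [0, 0.2], delay ∈ [−1, 1] min. Weights are uniform by default —
the most reproducible choice, since the original analysis tool's weighting
is undocumented — with frame-duration weighting available; at the
generator's noise level the two weightings move cortical V_T by well under
1%. Initialisation is a deterministic 8-point grid spanning one to two
orders of magnitude in each rate; every start runs at loose tolerance and
the winner is polished at xtol 1e−13. A fit that ends on a parameter bound
is flagged non-converged — a rate pinned at its lower bound (typically
k4 → 0 inflating BP_ND and V_T into the hundreds) marks an unidentifiable
fit, the same failure mode that forced the original analysis to discard a
V_T = 20.5 outlier and over half its k3/k4 values.

The five candidate configurations (1-/2-tissue × V_B free/fixed, plus
2-tissue fixed-V_B with fitted delay) are compared by the least-squares
Akaike score AIC = n·ln(WRSS/n) + 2p, where p counts free parameters (V_B
and delay only when free); ties break toward fewer parameters and a perfect
fit returns a −∞ sentinel with a warning.

## Logan graphical analysis

The plasma-input Logan plot regresses y(t) = ∫₀ᵗC_T/C_T(t) on
x(t) = ∫₀ᵗC_p/C_T(t) over frames whose mid-time is ≥ t* (default 20 min;
whether t* should gate frame starts, mids or ends is not specified by the
source analysis — mid-time is our choice). The tissue curve is first
blood-corrected, C_T = (C_meas − V_B·C_wb)/(1 − V_B) with V_B = 3.6%
(toggleable). Because frame values are frame averages, the cumulative
tissue integral to a frame boundary is exactly the running sum of
value×duration; the mid-time adds half the current frame. An earlier
trapezoid-on-mid-times scheme overestimated the slope by ~2% on noise-free
one-tissue data — above the analytic V_T, which the Logan estimator must
not exceed — and was replaced by the frame-sum form, which gives −0.0003%
(one-tissue) to −1.6% (two-tissue grid) errors, all non-positive as theory
requires. The plasma integral uses the input curve's own sampling
(trapezoid on its knots, exact for a piecewise-linear curve).

The classical negative noise bias of Logan slopes is second order in the
tissue noise. At the cohort generator's regional noise level it is below
0.05% and invisible against Monte-Carlo error; the dedicated bias study
therefore runs at noise_scale 0.3 (≈28% SD on the late frames, small-VOI /
voxel statistics) and draws zero-mean, unclipped noise in antithetic pairs,
which cancels the first-order slope fluctuation so 200 replicates resolve
the bias (≈ −0.2%, reliably negative across seeds).

## Reference-tissue models

SRTM models the target as R1·C_ref + (k2 − R1·k2a)·C_ref ⊛ e^(−k2a·t), with
k2a = k2/(1+BP_ND) the apparent efflux. It is solved by the basis-function
method: 64 logarithmically spaced k2a values in [0.006, 6] min⁻¹, a
two-parameter linear subproblem per basis, then bounded refinement of k2a
around the grid minimum. Near the top of the grid e^(−k2a·t) approaches a
delta function and the basis column becomes collinear with the reference
regressor, so the WRSS profile can drift below the physical minimum there;
the solver therefore prefers the best *interior local minimum* of the grid
profile and falls back to the global minimum — flagged non-converged when
on the boundary — only if none exists. Halving the grid spacing moves
BP_ND by far less than 0.5% on reference cases. The identities
k2a·(1+BP_ND) = k2 and k2′ = k2/R1 hold exactly by construction. On noisy
data with weak binding contrast the WRSS profile is nearly flat and
occasional fits wander to implausible k2a; these are visible in the
reported k2′ and are retained rather than silently repaired.

The Logan reference-tissue model regresses ∫₀ᵗC_T/C_T(t) on
[∫₀ᵗC_ref + C_ref(t)/k2′]/C_T(t) beyond the same t* = 20 (the source
analysis states one t* only; configurable); its slope is the distribution
volume ratio and BP_ND = DVR − 1. k2′ is handed off from SRTM per region by
default, with a per-subject-median option. No blood-volume correction is
applied inside reference-tissue models (standard practice). SRTM is exact
when target and reference are true one-tissue regions sharing V_ND
(recovery to machine precision in that case); on two-tissue targets in the
generator's kinetic regime it carries a residual +10–18% bias, and
inflating the reference V_ND deflates BP_ND, both tested directionally.

## Cohort statistics

Long-format tables (subject, group, region, method, parameter, value) feed:

* region-to-cerebellar-grey ratios over 50–60 min (exactly the last 600-s
  frame of the default schedule) and TAC areas (Σ value×duration, exact for
  frame averages);
* two-sided group contrasts — Welch's t by default (the groups differ in
  size and variance; whether the original analysis used Welch or Student
  is unstated, so Student's is available for strict replication);
* regional panels via a two-way (group × region) type-II ANOVA with
  Bonferroni-adjusted per-region Welch contrasts and star labels at
  0.05/0.01/0.001/0.0001;
* the k3/k4 outlier rule: values strictly above 1 are excluded, the
  boundary value kept;
* cross-method regression in the study's orientation (the two-tissue
  parameter regressed on the simpler method), reporting Pearson r, slope,
  intercept and percent bias under both conventions 100·(slope−1) and
  100·(1−1/slope), since the source analysis' wording does not fix one;
* an explicit V_T exclusion threshold (default 20.0) standing in for the
  study's informal removal of a V_T = 20.5 animal: unidentifiable k4 → 0
  fits otherwise leak V_T values in the hundreds into the regressions.

Under a 1000-replicate null simulation the Bonferroni-adjusted per-region
type-I error is ≈0.008, well inside the nominal 0.05.

## Synthetic-data generator

The generator emulates the study conditions:

* **Input function.** Parent plasma rises linearly to a peak at 0.5 min and
  washes out mono-exponentially at 0.1 min⁻¹; peak values 0.47 (wild-type)
  and 0.55 (transgenic) %ID/g reproduce the reported parent-plasma AUCs of
  ≈4.8 and ≈5.6 %ID/g·min. A faster washout would leave the late frames
  input-free, producing region-to-reference ratios of 2–6 driven by
  washout-rate differences instead of the ~1–2 the study reports. The
  parent fraction is (1−plateau)·e^(−rate·t)+plateau, calibrated to 0.18
  (wild-type) and 0.15 (transgenic) at 60 min; total plasma is parent/f(t)
  and whole blood total/1.2 (the plasma-to-blood ratio is unreported;
  constant 1.2 is our choice). Blood samples follow the study's 16-point
  schedule (5–105 s, then 2–60 min) with 3% measurement noise; parent
  fractions are measured at 5–60 min with SD 0.01.
* **Regional kinetics.** Each subject draws a non-displaceable volume V_ND
  shared across regions up to 1% jitter (wild-type 3.83 ± 0.55, transgenic
  4.53 ± 0.75 — so cortical V_T centres near 4.6 vs 5.8), a global flow
  factor (CV 8%) scaling a stable regional K1 pattern (≈0.38–0.42
  mL·cm⁻³·min⁻¹, 3% regional jitter), regional BP_ND, and k4 = 0.15 ± 0.02
  min⁻¹. k2 = K1/V_ND and k3 = BP_ND·k4 are derived. Sharing V_ND is what
  makes cerebellar grey (generated with k3 = 0 in both groups) a usable
  pseudo-reference; sampling all four rates independently per region would
  break that assumption and nothing in the reference-tissue analysis would
  work, on synthetic or real data alike. Generating cortical BP_ND means
  (0.18 wild-type, 0.24 transgenic) sit below the reported fitted values
  because SRTM's residual positive bias is part of the measurement: the
  *fitted* cortical SRTM BP_ND centres at ≈0.20/0.28 with paper-like
  spread, and brainstem at ≈0.07/0.12 against 0.08/0.14. k4 = 0.15 was
  fixed by this calibration requirement — at k4 = 0.06 the slow binding
  equilibration violates SRTM's one-tissue approximation so badly (+86%
  bias, SD ≈ 0.11) that no generating moments could reproduce the reported
  fitted ones.
* **TAC noise.** Zero-mean Gaussian per frame with
  SD = noise_scale·√(value/duration) (default 0.02), a count-statistics
  surrogate making variance inversely proportional to frame duration;
  negative values are clipped at zero with a recorded count.
* **Determinism.** A cohort is a pure function of its spec: seeds spawn
  per subject from one root `SeedSequence`, and regeneration is
  bit-identical. Ground truth is written to a separate, clearly named file
  and never appears in the observable tables.

What the generator does *not* emulate: image-domain effects (partial
volume, spill-over, reconstruction bias), violations of the shared-V_ND
assumption beyond the small jitter, multi-exponential plasma kinetics (a
multi-exponential option exists for stress-testing), tracer defluorination
and bone uptake, or within-group covariance between input and tissue
parameters. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated generative model, not robustness
to those real-data effects.

## Problem sizes of the validation studies

The self-validation studies (`petkin.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: a 39-point
parameter grid for the ODE oracle; 3 identifiable cases plus a null-binding
case for noise-free recovery; 5 parameter sets for noise-free Logan; 200
antithetic replicates for the Logan noise bias; 100 replicates per scenario
for AIC selection; 1000 replicates for the null calibration and 500 for
the power check; and 50 replicate cohorts (full default size, 11 vs 8) for
end-to-end detection, quantified through the pipeline's SRTM stage, with
bit-reproducibility checked on a full-method run. Detection means the
fitted cortical SRTM BP_ND group mean is higher in the transgenic group;
the Welch-test significance rate at these group moments (analytically
~75–85% power) is reported alongside.

## Known limitations

* k3/k4 from the two-tissue model is poorly identified at regional noise —
  faithfully so: roughly a third to a half of fits land on a bound or an
  implausible ratio, mirroring the original analysis' discarding of over
  half its k3/k4 values.
* SRTM/LRTM estimates on two-tissue targets carry the documented
  model-violation bias; cross-method regressions quantify, not remove, it.
* The AIC roster on default-noise cohort data often prefers the one-tissue
  model: the second exponential of weak binding is faint at regional
  noise. The model-selection acceptance study uses well-separated rates
  where the families are distinguishable.
* Blood-based fits inherit the 16-sample reconstruction of the input; its
  interpolation error biases V_T down by a few percent uniformly, which
  cancels in group contrasts and cross-method comparisons.
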