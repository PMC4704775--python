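# Methods

`vfmdi` predicts whether a defibrillation attempt during ventricular
fibrillation (VF) will restore a perfusing rhythm, using only a short
(9-second) ECG window ending immediately before the countershock, with an
optional capnography (PetCO2) channel. This note describes the model and
procedures, the choices made where the design was genuinely open, and what
the synthetic cohorts do and do not establish.

## Signal model and windowing

A pre-shock segment is the half-open window `[t_shock − 9 s, t_shock)` of a
single-lead ECG, carried with its own sampling rate (default 250 Hz for
synthetic data; the rate is always data, never assumed). VF has no P-QRS-T
structure: the waveform is an irregular oscillation whose dominant
frequency, amplitude and degree of organization carry prognostic
information. The package therefore characterizes segments in several
domains at once — nonlinear phase-space statistics, shift-invariant wavelet
subbands, time-domain descriptors — and lets a cross-validated classifier
integrate them ("multiple domain integration", MDI).

## Preprocessing

Two-stage adaptive filter:

1. **Smoothing.** Savitzky–Golay, degree-11 polynomials over 25-sample
   frames. SG kernels of this order are numerically fragile; the kernel here
   is built from a QR factorization of a Legendre design matrix on
   abscissae scaled to [-1, 1] and reproduces degree-≤11 polynomials to
   ~1e-14. Boundary samples use truncated one-sided windows.
2. **De-trending.** A wide cubic SG smoother (frames of 499 samples,
   clipped to the largest odd value not exceeding the segment) estimates
   the baseline — shifts, drifts and step artifacts — which is subtracted
   from the stage-1 output. Two non-obvious choices:
   * *Edges.* Fitting the raw oscillation in one-sided boundary windows
     leaks spurious baselines of several tenths of a millivolt; instead the
     baseline is computed on interior (full-window) positions and extended
     to the edges by polynomial extrapolation of the already-smooth
     interior curve. On a unit-amplitude 5 Hz sine the whole estimated
     baseline stays below 1% of the amplitude.
   * *Pass count.* The smoother may be reapplied until the inter-pass
     change falls below `base_tol` (default 1e-3 mV) or `base_passes_max`
     is reached. Empirically each extra pass widens the transition around
     step artifacts faster than it improves oscillation suppression
     (detrended-vs-clean correlation in a drift+step scenario: 0.991 after
     one pass, 0.984 after ten), so the default is a single pass; the
     iteration remains available in `FilterConfig`.

## Phase-space characterization

The scalar segment `p_n` is delay-embedded as
`P_k = (p_{k+(m−1)τ}, …, p_{k+τ}, p_k)` with dimension `m = 4` and delay
`τ = 8` samples, values adequate for 9-s VF windows: τ large enough that
coordinates are informative, small enough that the state retains memory.

**Maximal Lyapunov exponent.** Rosenstein's nearest-neighbour method: for
each point, the nearest neighbour at temporal separation beyond a Theiler
window (`m·τ` samples) is found, and the exponent is the least-squares slope
of the mean log divergence versus time, in 1/s. The fit window is
`[fit_start, fit_range]` steps; `fit_start = 0` by default (appropriate for
short noisy biological segments), while clean deterministic flows expose a
fast neighbour-relaxation transient that should be skipped — the Lorenz
cross-check in the test suite fits steps 60–150 and lands within 25% of a
two-trajectory (Benettin-style) divergence oracle. Positive exponents on
essentially all generated VF segments are what justifies the nonlinear
feature set.

**Quasi-periods.** Recurrence times of the trajectory into an ε-ball
(radius = `eps_fraction` × bounding-box diagonal, default 0.15) around
reference points, with the same Theiler window separating distinct visits;
entries whose sojourn may be truncated by the array edges are discarded.
Reference points are subsampled with a stride (default 5) — recurrence
statistics pool over references, so the stride trades sample size for
linear cost without biasing durations.

## QPD-PD features

The pooled quasi-periods are binned (default 0.05 s bins on [0, 1.5 s],
longer periods pooling in the last bin) and smoothed into a PDF by causal
convolution with an exponential kernel `e^{−t/4}` (t in seconds),
renormalized on a uniform grid. The kernel quantifies concentration: a
class whose quasi-periods cluster tightly produces a sharply peaked PDF.

**Prototype distances.** Features are distances `KD` from a segment's PDF
to the PDFs of a prototype set: C = 4 segments per outcome class. The
distance is the Jeffreys (symmetrized Kullback–Leibler) divergence on
floor-regularized common-grid PDFs (floor 1e-30, numerical safety only);
the interface is pluggable. Prototypes default to per-class KD medoids
computed inside the training fold only — a leakage-free automation of what
is, in clinical practice, a manual choice — with explicit IDs available as
an override.

**Parameter selection.** The scalar criterion

    sep = Σ_i [ mean(KD_i^B) − mean(KD_i^W) ] / max(Var_i^B, Var_i^W)

(B = opposite-class, W = own-class distances of prototype i, variances with
divisors C^B and C^W = own-class count − 1) scores a parameterization by
how far it separates the two prototype classes. As written the quantity is
not scale-invariant — `sep(s·KD) = sep(KD)/s` — and it is implemented
exactly in that form (property-tested). `select_parameters` maximizes sep
over a configurable grid (bin width, ε-fraction, Theiler window), skipping
degenerate grid points, and retains the full trace for diagnostics.

## Wavelet and time-domain features

Windowed segments shift; a decimated wavelet transform would make features
depend on where the cut fell. The decomposition here is a dual-branch
analytic stationary wavelet transform: a norm-preserving undecimated
orthogonal DWT (`db6`, 5 levels) of the signal and of its Hilbert
quadrature, paired into complex coefficients. This keeps the two properties
that motivate dual-tree-style complex transforms — near-perfect
reconstruction (exact from the real branch) and shift-robust subband
magnitudes — without depending on a specific published filter pair. The
signal is reflect-padded on both sides so the transform's periodic wrap
never touches the analysed support, and per-level statistics (energy, mean
and std of magnitude, normalized log-energy entropy; names
`dtcwt_L{k}_{stat}`) are computed on interior coefficients (margin =
min(filter support at the deepest level, n/4)), bounding the change of any
per-level energy under 1–4-sample shifts below 5%.

Time-domain descriptors: mean absolute amplitude, RMS, peak-to-peak (mV),
zero-crossing rate (1/s), median absolute slope (mV/s).

PetCO2, where available, contributes its window mean, linear-trend slope
and final value. The PetCO2 sub-analysis runs on the sub-cohort with usable
capnography (~13% of shocks); at that sample size a projection fitted on
~22 training rows over ~36 features is ill-posed and buries the three
capnography features, so both arms of the comparison (augmented and
ECG-only) use direct forward selection without projection.

## AMSA baseline

The comparator is the amplitude spectrum area,
`AMSA = Σ A_i·f_i` over 4–48 Hz (configurable), with `A_i` the single-sided
DFT amplitude spectrum. The band-pass is realized as an ideal zero-phase
frequency-domain mask: restricting the sum to in-band bins *is* the
band-pass, whereas an explicit IIR stage rings at its 4 Hz corner across a
finite segment and inflates the sum by tens of percent. The window default
is rectangular; with a taper, the spectrum is normalized by 2/N (total
amplitude mass) so a tone's AMSA is window-invariant to <2%.

## Feature space and statistical validation

Features live on incommensurate scales, so they are z-scored and projected
onto principal axes; components are kept until 99% of cumulative variance
(the remainder is treated as noise and discarded — typically a third or
more of the dimensions). Validation battery:

* per-feature two-class ANOVA (identical to a pooled t-test, `F = t²`) and
  Kruskal–Wallis (identical to Mann–Whitney–Wilcoxon for two groups,
  tie-corrected);
* a two-sample Hotelling T² (two-group MANOVA) with its exact F transform
  on the reduced orthogonal set, answering whether the feature set as a
  whole differs between classes;
* an accumulated false-positive probability `1 − Π(1 − p_i)` across batches
  of 40 features (independence approximation), for diagnostic plots rather
  than a fixed significance threshold.

## Classification and validation protocol

Twice-nested stratified 10-fold cross-validation. Within each outer
training set: standardization and projection are fitted (never on test
folds); level 2 runs greedy forward feature selection (cap 20, ties to the
lower index) scored by mean inner-CV AUC; level 1 grid-searches
hyperparameters on the selected subset; the winner is refitted on the full
outer-train set. Prototype selection for the KD features is likewise redone
inside each outer training fold (`fold_features_fn` hook). Folds can be
grouped by patient (default in the cohort pipeline) so multiple shocks from
one patient never straddle a fold boundary.

The default classifier is stagewise additive logistic regression
(LogitBoost with depth-1 regression stumps, implemented in-repo; working
responses clipped at ±4). The comparison suite: random forest (100 trees,
80% feature fraction), L2 ("Gaussian-prior") logistic regression,
back-propagation network (SGD, 500 iterations, learning rate 0.3, momentum
0.4), and AdaBoost over entropy-criterion CART trees (100 iterations) as
the functional equivalent of boosted C4.5.

Reported metrics: out-of-fold ROC AUC (trapezoid; equals Mann–Whitney
concordance), accuracy at the best threshold, and
sensitivity/specificity/accuracy at 80% and 90% sensitivity targets (the
largest threshold whose sensitivity meets the target).

## Synthetic cohorts

No clinical recordings ship with the package; the generator produces
cohorts with the statistical structure the method assumes. A VF segment is
a sinusoid (plus a weak second harmonic) frequency-modulated by a logistic
map (r = 3.99, sampled at 25 Hz, interpolated, zero-meaned per segment so
the dominant frequency is identifiable), plus pink noise, linear drift, and
occasional ±1 mV step artifacts. Cohort defaults are a realistic
out-of-hospital arrest registry scale: 153 patients / 358 shocks, success
rate 140/358, PetCO2 available for 48/358 shocks (tests and the acceptance script use 200-shock cohorts
as their default problem size).

Class structure was chosen once to reproduce the *relationships* the method
is built around, not to make the task easy: wide within-class overlap in
dominant frequency (5.1 ± 0.7 vs 4.3 ± 0.7 Hz) and amplitude (1.0 ± 0.22
vs 0.82 ± 0.22 mV), with most class information carried by waveform
organization (modulation depth 0.20 vs 0.45). Under these conditions the
single-feature AMSA baseline is only a moderate discriminator (AUC ≈ 0.6 at
n = 200) while the integrated model reaches AUC ≈ 0.98 — the qualitative
ordering that motivates multi-domain integration. PetCO2 levels and trends
are strongly class-dependent (34 vs 17 mmHg; rising vs flat), so the
PetCO2-augmented model on the sub-cohort dominates the ECG-only model.

What passing tests on these cohorts does **not** show: robustness to CPR
compression artifacts, electrode motion, inter-patient morphology
differences beyond the modelled parameters, or calibration of predicted
probabilities on real cardiac-arrest data. The generator's chaos drive
guarantees positive Lyapunov exponents by construction; on real VF this is
an empirical finding, not a given.

## Numerical choices and degenerate inputs

* Variance floor 1e-12 in `sep` before declaring degeneracy; probability
  floor 1e-30 in KD.
* Constant signals raise degenerate-input errors in embedding statistics
  (zero attractor diameter); empty recurrence samples raise an
  empty-density error at the histogram stage, and a no-recurrence sample
  carries a warning flag.
* Ties in forward selection and in sep-grid argmax resolve to the first
  (lowest-index / first-in-grid) candidate, making selection deterministic.
* All stochastic procedures fan out from one master seed; cohort generation
  is a pure function of its spec.

## Problem sizes and runtime

Default test/acceptance problem sizes — 200-shock cohorts, inner-CV fold
count 3, forward-selection cap 6, 30 boosting iterations — were chosen so
the full acceptance run completes in a few minutes on one CPU while leaving
every ordering tested far from its decision boundary. The full
10-fold/20-feature protocol is the package default for real use
(`ModelSpec`, `nested_cv(k=10)`).

## Known limitations

* The quasi-period extraction operator and the KD distance are
  reconstructions from standard nonlinear-dynamics practice (recurrence
  times; Jeffreys divergence); both are pluggable because the original
  operator definitions are not public.
* Single-segment Lyapunov estimates on 9-s windows are noisy; they are used
  as a chaoticity screen, not as a calibrated physiological quantity.
* The latency budget (<80 ms per prediction) covers classification of an
  assembled feature vector, not feature extraction itself.
* `sep`'s scale-dependence means its absolute values are comparable only
  within one KD parameterization.
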