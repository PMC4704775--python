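# vfmdi

Prediction of ventricular-fibrillation (VF) defibrillation outcomes from
short pre-countershock ECG segments.

During cardiac arrest, defibrillation attempts are usually timed by
protocol rather than by the heart's readiness to convert; failed shocks
interrupt compressions and add electrical burden. `vfmdi` implements a
*multiple-domain integrative* (MDI) approach to this decision problem: a
9-second ECG window ending just before the shock is characterized in
several domains at once, and a nested cross-validated classifier predicts
whether the shock will restore a perfusing rhythm (ROSC-style binary
outcome). It is aimed at researchers in resuscitation science and
biomedical signal processing who want a reproducible, testable reference
pipeline.

## The model

Each pre-shock segment `p_n` is processed as follows.

1. **Filtering** — Savitzky–Golay smoothing (degree 11, 25-sample frames)
   followed by subtraction of a wide cubic SG baseline estimate (frames
   ≤ 499 samples): removes high-frequency noise, drift and step artifacts
   while preserving VF morphology.
2. **Phase space** — delay embedding
   `P = [p_n, p_{n−τ}, …, p_{n−(m−1)τ}]` with `m = 4`, `τ = 8`. The maximal
   Lyapunov exponent λ (Rosenstein estimator) screens for chaoticity
   (λ > 0 on VF). Recurrence times of the trajectory into ε-balls — the
   *quasi-periods* — are binned and smoothed with a causal exponential
   kernel `e^{−t/4}` into a quasi-period density (QPD).
3. **QPD-PD features** — Jeffreys divergences `KD` between a segment's QPD
   and the QPDs of 8 class-prototype segments (4 per outcome class,
   training-fold medoids). QPD parameters are selected by maximizing the
   class-separation criterion
   `sep = Σ_i [mean(KD_i^B) − mean(KD_i^W)] / max(Var_i^B, Var_i^W)`.
4. **Wavelet + time features** — per-level magnitude statistics of a
   shift-robust analytic stationary wavelet decomposition (5 levels), plus
   RMS, peak-to-peak, zero-crossing rate, median absolute slope.
5. **Reduction and validation** — z-scoring, projection onto principal
   axes keeping 99% of cumulative variance; per-feature ANOVA (`F = t²`)
   and Kruskal–Wallis, two-group MANOVA (Hotelling T²) on the reduced set.
6. **Classification** — twice-nested stratified 10-fold cross-validation:
   forward feature selection by inner-CV AUC (level 2), hyperparameter
   tuning (level 1), refit per outer fold. Default classifier: stagewise
   additive logistic regression (LogitBoost with stumps); random forest,
   Bayesian-prior logistic regression, back-propagation network and
   AdaBoost trees are available. Reported: out-of-fold ROC AUC, accuracy,
   and sensitivity/specificity at 80%/90% sensitivity targets.

The single-feature **AMSA** baseline (`Σ A_i·f_i` over 4–48 Hz of the DFT
amplitude spectrum) is included as the comparator.

Because no clinical recordings are distributable, the package ships a
first-class synthetic-cohort generator (`vfmdi.synthetic`): chaotic
frequency-modulated VF waveforms with class-dependent dominant frequency,
amplitude and organization, pink noise, drift and step artifacts, and an
optional class-dependent PetCO2 channel. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
from vfmdi import CohortSpec, generate_cohort, MDIModel, ModelSpec

records, truth = generate_cohort(CohortSpec(n_patients=40, n_shocks=80, seed=7))
model = MDIModel.from_records(records, spec=ModelSpec(max_features=5),
                              k=5, inner_k=3)
res = model.fit(seed=0)
print(res.summary())
```

prints

```
MDI nested cross-validation summary
===================================
algorithm        : ADDITIVE_LOGISTIC
shocks           : 80 (36 successful / 44 unsuccessful)
outer folds      : 5   seed: 0
ROC AUC          : 0.991
best accuracy    : 0.975 (threshold 0.82)
at 80% sensitivity: spec 0.977, acc 0.900 (threshold 0.99)
at 90% sensitivity: spec 0.977, acc 0.950 (threshold 0.95)
```

Every probability is an out-of-fold prediction: the model scoring a shock
never saw that shock (or that patient — folds are grouped by patient), its
prototypes, projection and feature subset having been fitted on the other
folds. `ROC AUC` is the ranking quality of those held-out probabilities;
the `at N% sensitivity` rows give the specificity and accuracy available
when the decision threshold is set to catch N% of truly shockable states.

A thin CLI mirrors the library:

```bash
vf-mdi simulate --out cohort/ --seed 1          # write recordings + annotations
vf-mdi features --out features.csv --seed 1     # full MDI feature table
vf-mdi amsa     --out amsa.csv --band 4:48      # per-shock AMSA values
vf-mdi evaluate --out eval.json --seed 1        # nested-CV evaluation
```

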