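# radsurv

CT radiomics and Cox-likelihood neural networks for predicting
progression-free survival (PFS) after EGFR-TKI therapy in advanced
non-small-cell lung cancer.

About half of *EGFR*-mutant NSCLC patients on first-line tyrosine kinase
inhibitors progress within a year. Identifying, before treatment, who will
progress early — and *when* their risk becomes elevated — helps plan
follow-up and second-line strategies. `radsurv` implements an end-to-end
pipeline from a pretreatment chest CT volume with a tumor mask to a
personalized survival curve and a categorical **risk-of-progression
period**, together with a synthetic-cohort generator so every stage is
testable without clinical data.

## The method

1. **Preprocessing.** Resample volume and ROI to isotropic 1 mm³, Z-score
   the intensities, and apply one-level separable low/high-pass wavelet
   filtering along each axis (undecimated Coiflet-1), yielding nine image
   sets: original + LLL … HHH.
2. **Radiomics.** Per image set, 14 histogram + 22 GLCM + 16 GLRLM +
   12 LBP features on the in-mask voxels, plus 17 mesh/PCA shape features
   of the mask — **593 features** per tumor. GLCM/GLRLM aggregate the 13
   unique 3-D directions at distance 1; key features include
   IDMN = Σᵢⱼ p(i,j) / (1 + (i−j)²/N_g²) (local homogeneity) and
   compactness₂ = 36π·V²/A³ (1 for a sphere).
3. **Feature selection.** On the training split only: univariate Cox
   screens (radiomic) and chi-squared screens against good/poor tumor
   control (clinical) at p < 0.1, then sequential forward selection scored
   by cross-validated concordance.
4. **Risk model.** A feed-forward network h(x) trained on the average
   negative log Cox partial likelihood
   L = −(1/N_E) Σᵢ:event [hᵢ − log Σ_{Tⱼ≥Tᵢ} exp(hⱼ)] + λ‖W‖²
   (Breslow ties, full-batch Adam, learning-rate decay, dropout, early
   stopping). Three variants share one split: clinical, radiomic, combined.
   The Breslow baseline S₀ turns scores into personalized curves
   S(t|x) = S₀(t)^exp(h(x)).
5. **Evaluation.** Harrell's C; time-dependent ROC at 3/12/18/24 months
   (cases progressed by t, controls progression-free past t, marker S(t));
   paired bootstrap comparison of models; log-rank on predicted risk groups.
6. **Risk-of-progression period.** The four Youden-optimal thresholds S*
   anchor a Weibull reference curve S_ref(t) = exp(−(t/λ)^k) via
   complementary log-log least squares. The first time a patient's curve
   drops below S_ref locates their risk period in
   {<3, 3–12, 12–18, 18–24, >24 months}; the signed area between the curves
   summarizes overall risk.

The synthetic cohort emulates the study conditions: ellipsoidal tumor
phantoms with spherical-harmonic lobulation (shape signal) and Gaussian
random-field texture (homogeneity signal), clinical covariates drawn from
published cohort proportions (270 patients), and Weibull
proportional-hazards PFS with uniform censoring calibrated to the
~11.5-month median-PFS regime.

## Worked example

```bash
python examples/05_risk_period.py
```

```
reference curve: S_ref(t) = exp(-(t/19.2)^1.20)
  long PFS (curve above reference)         area= +1.81  crossing=none      risk period: >24 months
  moderate PFS (crosses at ~8 months)      area= -0.96  crossing=8.0 m     risk period: 3-12 months
  short PFS (below from the start)         area= -2.88  crossing=0.0 m     risk period: <3 months
```

The reference curve is fitted through the four ROC thresholds; a positive
area means the patient's predicted survival dominates the reference (low
risk), and the first downward crossing sets the risk-period category.

`examples/04_evaluate_time_dependent.py` shows the horizon metrics feeding
those thresholds:

```
horizon   AUC   sens   spec   S*    cases/controls
    3 m  0.779  0.722  0.703  0.866  18/101
   12 m  0.686  0.787  0.533  0.609  47/60
   18 m  0.756  0.754  0.703  0.457  65/37
   24 m  0.714  0.703  0.714  0.375  74/21
```

The other examples cover phantom feature extraction (`01`), cohort
generation (`02`), network training and survival curves (`03`), and the
full three-model pipeline with artifacts on disk (`06`).

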