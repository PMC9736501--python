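# graspnirs

Whole-head functional near-infrared spectroscopy (fNIRS) analysis of a
block-design motor-grasping task in Parkinson's disease, built as a tested,
fully reproducible pipeline over synthetic data with known ground truth.

Continuous-wave fNIRS measures changes in oxy- and deoxyhemoglobin
(Δ[HbO2], Δ[HbR]) through scalp optodes while participants repeatedly squeeze
a ball with the left or right hand (10 s task, 20 s rest, 10 trials per side).
The package implements the full analysis chain a clinical fNIRS study of this
design needs, for two severity groups (early ePD vs moderate mPD):

1. **Preprocessing** — optical density, wavelet motion-artifact correction,
   0.01 Hz zero-phase high-pass, PCA removal of the shared superficial (scalp)
   signal, and the modified Beer–Lambert inversion
   ΔOD(λ) = [ε_HbO2(λ)Δ[HbO2] + ε_HbR(λ)Δ[HbR]]·d·DPF(λ).
2. **Subject-level GLM (SLSA)** — a design of canonical double-gamma HRF
   regressors (peak at 6 s) plus temporal derivatives, fitted per channel by
   AR(p)-prewhitened iteratively reweighted least squares (AR-IRLS: BIC-chosen
   Yule–Walker AR fit to the residuals, Tukey-bisquare robust weighting), with
   task-vs-rest t contrasts and Benjamini–Hochberg FDR across channels.
3. **Group level (GLSA)** — per channel, the cell-means linear mixed-effects
   model `beta ~ −1 + group:cond + (1|subject)` (REML), giving per-group
   activation maps and ePD-vs-mPD contrast maps (positive t = higher
   activation in the early group).
4. **ROI correlation analysis (ROI-CA)** — channels significant in the group
   contrast are intersected with 10 cortical regions (bilateral sensorimotor,
   primary/secondary visual, dorso-/ventrolateral prefrontal), subject betas
   are averaged over them, and the averages are correlated with clinical
   variables (age, CRIQ, disease duration, UPDRS, Stroop scores) by Spearman's
   ρ with an age-partialled companion.

Since clinical recordings of this kind are private, the package ships a
first-class synthetic-study generator (`graspnirs.simulate`) producing
dual-wavelength intensities with planted hemodynamic responses, AR +
physiological noise, a superficial component, motion artifacts, and clinical
covariates rank-coupled to a chosen region's response amplitude — with a
ground-truth sidecar that every test asserts against. See
[docs/methods.md](docs/methods.md) for the model details.

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over the
library; outputs land in `results/study/`):

```bash
python analysis/01_simulate_study.py --seed 7
python analysis/02_preprocess_example.py --seed 7
python analysis/03_subject_glm.py --seed 7
python analysis/04_group_maps.py
python analysis/05_roi_correlations.py
```

which prints, for the 39-subject default study:

```
simulated 13 ePD + 26 mPD subjects, 102 channels, 1211 samples each
planted nonzero HbO2 responses on 80 channels across 8 regions
...
planted contralateral betas: median relative bias -9.6%, detection at q<0.05: 92%
...
L-SMN right-grasp HbO2 activation (ROI-averaged t):
  ePD: t = +12.01
  mPD: t = +16.05
ePD-vs-mPD right-grasp HbO2 contrast: L-SMN mean t = +2.63; 52 channels p < 0.05 map-wide
...
150 ROI x variable correlations computed; 11 significant at p < 0.05:
   R-VIS2 hbo RG x    updrs: rho = +0.621 (p = 0.000), age-partialled +0.622
```

Reading this: the left sensorimotor region (L-SMN) activates strongly under
the contralateral right-grasp task in both groups; the positive group-contrast
t recovers the planted ePD > mPD amplitude difference (0.30 vs 0.20 µM); and
the ROI correlation step recovers the planted Spearman coupling (ρ = 0.5)
between the synthetic UPDRS score and the R-VIS2 response amplitude, with the
age-partialled coefficient essentially unchanged. Subject-level recovery of
the planted betas is close to unbiased with high detection power.

The same pipeline is scriptable in one call (`graspnirs run-all --seed 7 --out
out/`) or from Python:

```python
from graspnirs.pipeline import PipelineConfig, run_all
run_all(PipelineConfig(seed=7), "out/")   # five TSV tables + manifest.json
```

Reruns with the same config and seed are byte-identical.

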