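# pasa — photoacoustic spectral analysis of tissue composition

`pasa` is a Python implementation of a machine-learning photoacoustic
spectral analysis (PASA) pipeline for probing the biochemical composition of
soft tissue — specifically, collagen remodeling of the extracellular matrix
that accompanies breast carcinogenesis. It is aimed at researchers in
biomedical photoacoustics and spectroscopic machine learning who want a
tested, reproducible reference for the full analysis chain, exercised end to
end on a synthetic data generator that emulates a two-arm (normal vs
cancerous) murine study.

## The method

A tunable pulsed laser scans the NIR-II window, 51 wavelengths from 1200 to
1700 nm in 10 nm steps, where collagen, water and lipid dominate optical
absorption and hemoglobin is nearly transparent. Each laser shot produces an
ultrasonic pressure transient recorded on a sample channel and on a
blackbody reference channel that tracks pulse energy. Per wavelength λ the
pipeline computes the **area of power spectral density**

    APSD(λ) = ∫_{f0}^{f1} p(f, λ) df,     f0 = 1 MHz, f1 = 4 MHz

where `p(f, λ)` is the sample signal's Welch power spectral density after
division by the blackbody peak-to-peak amplitude and compensation by the
hydrophone frequency response. APSD is proportional to absorbed optical
power, hence to chromophore content; the 51 values form one APSD spectrum
per sample. On top of the spectra the package provides:

- **Waveband partitioning** — z-scored wavelength profiles are clustered
  agglomeratively (Euclidean distance, complete linkage, cut at k = 3) and
  each cluster is assigned the chromophore with maximal mean normalized
  absorption, yielding collagen-, water- and lipid-dominated wavebands.
- **Correlation networks** — Spearman correlation of APSDs between every
  wavelength pair, thresholded at SCC > 0.9, gives an unweighted wavelength
  network; WalkTrap community detection and normalized betweenness
  centrality characterize how collagen co-varies with the other
  biomacromolecules.
- **GA wavelength selection** — a genetic algorithm (population 64, 50
  generations, 100 replicate runs, median culling, two-point crossover)
  minimizes the cross-validated RMSE of a linear regression of the 0/1
  class response, yielding per-wavelength inclusion frequencies and a best
  feature subset.
- **Classification** — KNN, PLSDA (with Q-residual / Hotelling-T² outlier
  screening and a Gaussian decision threshold) and RBF-SVM discriminant
  analysis with a log-uniform c/γ grid search, validated by stratified
  10-fold cross-validation with confusion matrices and pooled ROC/AUC.

## Worked example

```python
import numpy as np
from pasa import (
    GAConfig, GeneratorConfig, evaluate, generate_dataset, make_classifier,
    process_dataset, run_ga, stratified_kfold,
)

cfg = GeneratorConfig()                       # 51 wavelengths, 250 MHz sampling
records = generate_dataset(50, 50, cfg, seed=1)
spectra = process_dataset(records)            # APSD spectra, one row per sample

y = spectra.binary_response()                 # cancer = 1, normal = 0
ga = run_ga(spectra.values, y, GAConfig(runs=20, generations=30, seed=1),
            spectra.wavelengths)
print("feature wavelengths:", ga.best_wavelengths().astype(int).tolist())

plan = stratified_kfold(y.astype(int), k=10, seed=1)
feature = spectra.select_wavelengths(ga.best_wavelengths())
report = evaluate(feature.values, y.astype(int), make_classifier("svmda", seed=1), plan)
cm = report.pooled_confusion
print(f"accuracy {cm.accuracy_pct:.0f}%  sensitivity {cm.sensitivity_pct:.0f}%  "
      f"specificity {cm.specificity_pct:.0f}%  AUC {report.auc:.3f}")
```

prints

```
feature wavelengths: [1330, 1340, 1370, 1440, 1460, 1490, 1500, 1550, 1560, 1600, 1630, 1640, 1670]
accuracy 87%  sensitivity 86%  specificity 88%  AUC 0.938
```

i.e. on this synthetic study the GA distills 51 scan wavelengths down to 13
(over half from the collagen-dominated wavebands), and an RBF-SVM on those
feature wavelengths separates the two tissue classes with 87% pooled
test accuracy — above the 82% the same classifier reaches on full-range
spectra, the direction expected when informative wavebands are diluted by
redundant ones.

The same analysis is available from the shell:

```sh
pasa run-all --seed 1 --out runs/demo       # simulate → ... → classify
pasa select --spectra runs/demo/spectra.csv --runs 100 --generations 50 \
            --seed 11 --out runs/demo/ga
```

## Layout

- `src/pasa/synth.py` — synthetic two-channel measurement generator
- `src/pasa/spectral.py` — filtering, calibration, Welch PSD, APSD spectra
- `src/pasa/unsupervised.py` — wavebands, correlation networks, communities
- `src/pasa/ga.py` — genetic-algorithm wavelength selection
- `src/pasa/classify.py` — KNN / PLSDA / SVMDA with cross-validated reports
- `src/pasa/pipeline.py`, `src/pasa/cli.py` — orchestration and the `pasa` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
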