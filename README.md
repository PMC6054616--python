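# fluorostage

Staging of liver fibrosis from tissue autofluorescence spectra.

Under 410 nm excitation, liver tissue emits a broad fluorescence spectrum
shaped by a handful of endogenous fluorophores — NADH (~470 nm), FAD
(~500 nm), lipofuscin-like lipopigments (~590 nm), protoporphyrin IX
(~630 nm) and coproporphyrin (~670–690 nm) — and reshaped by hemoglobin
absorption along the photon path.  As fibrosis progresses these signatures
shift in characteristic ways: the FAD peak red-shifts (control ≈ 501 nm,
mild ≈ 505 nm, moderate ≈ 512 nm, returning to ≈ 502 nm on reversal), the
lipopigment band grows, the coproporphyrin band blue-shifts from 690 to
670 nm, and total hemoglobin falls.  `fluorostage` implements the complete
analysis pipeline for such spectra, plus a forward simulator that generates
group-labeled spectra with exactly this statistical structure, so every
stage is testable without measured data.

The pipeline stages:

1. **Preprocessing** — resampling to a common 310-point grid (441–750 nm,
   1 nm) and normalization of each spectrum to its maximum in the
   500 ± 10 nm window.
2. **Gaussian band decomposition** — each spectrum is modeled as
   `S(λ) = Σₖ Aₖ exp(−(λ−μₖ)²/2σₖ²)` and fitted by bounded trust-region
   least squares (the bound-respecting Levenberg–Marquardt variant),
   reporting per band the center μ, amplitude A, FWHM = 2√(2 ln 2)·σ and
   area = A·σ·√(2π), with χ² the sum of squared residuals.
3. **Hemoglobin index** — 500 and 570 nm are isosbestic points of
   hemoglobin, so the index `ln I(500)/I(570)` tracks total hemoglobin
   concentration independently of oxygen saturation (under Beer–Lambert
   attenuation it is exactly linear in concentration).
4. **Classification** — mean-centered PCA (components retained to 95%
   cumulative variance, minimum 2), then for each lesion pair a Fisher
   linear discriminant `w ∝ S_w⁻¹(m₊ − m₋)` on the PC scores, centered so
   the cutoff is 0; sensitivity/specificity, threshold-swept ROC with
   trapezoidal AUC (= Mann–Whitney statistic), and a 2-D multiclass Fisher
   map with 2-SD confidence ellipses and a nearest-centroid confusion
   matrix.
5. **Statistics** — pairwise one-way ANOVA on band intensities, band areas
   and the hemoglobin index, flagged at p < 0.05 and p < 0.005.

## Worked example

```python
import fluorostage as fs
from fluorostage.peaks import fit_dataset
from fluorostage.hemoglobin import thc_group_summary
from fluorostage.classify import classify_dataset

ds = fs.generate_dataset(n_per_group=60, seed=17)   # 4 groups x 60 spectra
norm = fs.normalize_dataset(ds)

peaks = fit_dataset(norm)
print(peaks[peaks.band == "FAD"].groupby("group").center_nm.mean().round(2))
print(thc_group_summary(norm)[["group", "median"]].round(3))

res = classify_dataset(norm, n_train=50, n_valid=10, seed=17)
rep = res.pairs[("moderate", "reversal")]
print(rep.training.sensitivity, rep.training.specificity, rep.merged_auc)
```

prints

```
group
control     501.18
mild        505.03
moderate    511.94
reversal    502.12
```

— the mean fitted FAD centers recover each stage's characteristic position
from 60 noisy spectra per group;

```
   group  median
 control   3.959
    mild   3.134
moderate   2.328
reversal   3.721
```

— the hemoglobin index medians are ordered control > reversal > mild >
moderate, the decrease with active fibrosis and partial recovery on
reversal that the index is designed to detect; and

```
100.0 100.0 1.0
```

— the moderate-fibrosis vs reversal pair separates completely at the 0
cutoff (training sensitivity and specificity 100%, ROC AUC 1.0).

The same pipeline runs from the shell:

```sh
fluorostage run --seed 17 --out results/
fluorostage simulate --n-per-group 60 --seed 17 --out data/
fluorostage classify --in data/manifest.csv --train 50 --valid 10 --seed 17 --out report.csv
```

`fluorostage run` writes `peaks.csv`, `hemoglobin.csv`, `classification.csv`,
`roc_points.csv`, `ellipses.csv`, `confusion_matrix.csv`, `anova.csv` and a
`run_summary.json` recording the full configuration including the seed.
Measured spectra can be supplied as two-column CSVs
(`wavelength_nm,intensity`) listed in a manifest CSV
(`spectrum_id,group,animal_id,file`).

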