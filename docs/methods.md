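# Methods

## Forward model

A simulated emission trace on the standard grid (441–750 nm inclusive,
1 nm spacing, 310 samples) is

```
S(λ) = [ Σₖ Aₖ exp(−(λ−μₖ)²/(2σₖ²)) ] · exp(−c·L·(s·ε_oxy(λ) + (1−s)·ε_deoxy(λ))) + η(λ)
```

a sum of Gaussian fluorophore bands attenuated by hemoglobin under
Beer–Lambert with a fixed effective path length `L`, plus i.i.d. Gaussian
noise `η` with standard deviation `noise_sd` × the peak of the noiseless
signal, clipped at zero.  The model assumes a single effective photon
path (no radiative transfer), purely Gaussian emission bands, and
multiplicative, wavelength-dependent absorption as the only distortion.

The grid starts at 441 nm: the emission window is quoted as 440–750 nm
with 310 samples, and 441–750 inclusive at 1 nm is the unique such grid
(440–750 inclusive would hold 311).

### Extinction curves

`ε_oxy` carries absorption features at 542 and 577 nm (the oxyhemoglobin
Q bands), `ε_deoxy` a single band at 555 nm.  These are smooth parametric
stand-ins, not literature tabulations; their defining constraint is the
isosbestic construction: the deoxy curve is affinely rescaled so the two
curves agree *exactly* at 500 and 570 nm, with ε(570) > ε(500).  This
makes the ratio I(500)/I(570) of any simulated spectrum independent of
oxygen saturation by construction, which is the property the hemoglobin
index exploits, and makes the log-index exactly linear in `c` on
noiseless spectra (slope `L·(ε(570)−ε(500))`).

The 542 nm feature is deliberately weaker than the 577 nm feature
(relative amplitudes 0.45 : 1.0, both σ = 9 nm; deoxy 1.05 at σ = 13 nm,
baseline 0.02).  This keeps the attenuation nearly flat beneath the
470/500 nm emission complex while preserving a clearly visible absorption
dip near 560 nm and a large ε(570)−ε(500) contrast.  A broad-band Gaussian
multiplied by attenuation with local log-slope β has its apparent center
displaced by ≈ −β·σ², so any appreciable extinction slope under the FAD
band would systematically displace the *fitted* FAD center away from the
generating μ — and the decomposition stage intentionally does not model
the dip.  The flat-blue extinction shape, together with the band widths
below, keeps that displacement well under the 1 nm scale at the default
concentrations; this was verified on noiseless forward-model fits when
the defaults were frozen.

### Stage presets

| group    | FAD μ (nm) | lipopigment A | porphyrin A | copro μ / A | c (Hb) |
|----------|-----------|---------------|-------------|--------------|--------|
| control  | 501       | 0.10          | 0.060       | 690 / 0.050  | 0.30   |
| mild     | 505       | 0.18          | 0.120       | 670 / 0.100  | 0.12   |
| moderate | 512       | 0.30          | 0.160       | 670 / 0.140  | 0.06   |
| reversal | 502       | 0.11          | 0.065       | 690 / 0.055  | 0.21   |

All groups share FAD amplitude 1.0 and an NADH band at 470 nm (amplitude
0.45–0.55).  The presets encode the stage signatures: FAD red-shift with
fibrosis severity and near-return on reversal; lipopigment growth with
severity (control ≈ reversal < mild < moderate); coproporphyrin at
690 nm in control/reversal but 670 nm in fibrotic livers; hemoglobin
concentration falling with active fibrosis and partially recovering on
reversal (moderate < mild < reversal < control).  The concentration
values are dimensionless and chosen for ordering and clear group
separation only — no absolute calibration to g/L is attempted.

Band widths are σ = 16 nm (FAD), 11 nm (NADH), 12 nm (lipopigments) and
8 nm (porphyrins).  Widths are a free choice of the generator (no
measured widths exist to emulate); they were set so that (a) the 470 and
500 nm bands overlap into the single broad blue complex seen in liver
emission while remaining identifiable to the fitting stage beneath the
unmodeled hemoglobin dip, and (b) the apparent maximum of the blue
complex in a noiseless control spectrum sits at the FAD position within
the 1 nm grid.  They are config-overridable per group.

Defaults `noise_sd = 0.005` (0.5% of peak — measured spectra of this kind
are smooth), saturation `s = 0.75`, `L = 1`.

### Dataset structure

`generate_dataset` produces `n_per_group` spectra per group (default 60,
emulating 5 animals × 12 measurement sites).  Spectra are assigned
round-robin to 5 virtual animals per group; each animal carries an
independent log-normal amplitude factor per band (sd 0.05) so repeated
sites within one liver are correlated.  The RNG stream is split by
(seed, group, animal/spectrum counter), so the dataset is bit-reproducible
from the seed for any size.

### What the generator does not emulate

No scattering or wavelength-dependent collection efficiency, no baseline
or dark-current drift, no non-Gaussian band shapes, no within-animal site
heterogeneity beyond i.i.d. noise, and no class overlap beyond what the
noise and animal effects induce.  The default group separations are
larger relative to noise than real staging data would give: the pairwise
classifiers separate all four pairs perfectly, where measured data
reported perfect separation only for the most distinct pair.  Passing
tests therefore demonstrate correctness of the pipeline's computations
and the recoverability of the encoded signatures — not classifier
performance to be expected on real spectra.

## Numerical choices

- **Normalization**: the window is the closed interval [490, 510] nm on
  grid points; the raw (unsmoothed) window maximum is used.  Degenerate
  spectra (nonpositive window maximum) raise.  Normalization is
  idempotent and scale-invariant.
- **Band fitting**: bounded nonlinear least squares (`scipy`'s
  trust-region reflective method, analytic Jacobian), unweighted
  residuals over the full grid, `ftol = xtol = 1e-8`, at most 500
  function evaluations.  Non-convergence sets `converged=False` rather
  than raising; a singular Jacobian returns the initial guess flagged as
  failed.  Fitted bands are reported sorted by center, names reassigned
  greedily by nearest library center so fluorophore labels stay
  meaningful if bands swap.  The default library starts at 470/500/590/
  630/670 nm with ±15 nm center bounds, except coproporphyrin widened to
  [655, 700] nm to admit the 690 nm control position.  The hemoglobin dip
  is *not* part of the fit model; localized residual structure near
  560 nm is expected.
- **Hemoglobin index**: intensities read at the exact 500 and 570 nm grid
  points; the natural log of the ratio is reported (exactly linear in
  `c`), alongside the raw ratio.  Box-plot summaries use linear
  percentile interpolation.
- **PCA**: mean-centered, full SVD; retained components are the smallest
  leading set reaching 95% cumulative explained variance, never fewer
  than 2.  An all-identical matrix raises a degenerate-data error.
- **Pairwise LDA**: Fisher direction `S_w⁻¹(m₊ − m₋)` on PC scores with
  the pooled within-class scatter; scores shifted so the midpoint of the
  class mean scores is 0, the more advanced lesion of the pair on the
  positive side (severity order control < reversal < mild < moderate).
  A singular or ill-conditioned scatter falls back to a ridge-regularized
  inverse with a warning.  A score of exactly 0 classifies as the
  positive (diseased) class — ties favor sensitivity.
- **Validation**: validation spectra are projected through the training
  PCA mean/loadings and the training discriminant; nothing is refit.
- **ROC**: thresholds swept over all distinct scores; trapezoidal AUC,
  equal to the Mann–Whitney statistic with ties counted one half.  Each
  pair's headline AUC is computed on the pooled training + validation
  scores (the per-role AUCs are also reported).
- **Multiclass map**: generalized eigendecomposition `S_b v = λ S_w v`
  (tiny ridge on `S_w` for numerical safety), two leading discriminant
  dimensions kept; per group the centroid, covariance, 2-SD ellipse
  (membership = Mahalanobis distance ≤ 2) and a nearest-centroid
  confusion matrix.  Ellipse membership and the confusion matrix are both
  reported because "inside the ellipse = true positive" is not a standard
  reading; the conventional matrix is the safer summary.
- **ANOVA**: classical fixed-effects F with df (k−1, N−k); zero
  within-group variance with unequal means reports F = ∞, p = 0, flagged.
  Observations are treated as independent (the per-animal structure is
  preserved in the tables for a future clustered analysis).  No
  multiple-testing correction; significance flagged at both 0.05 and
  0.005.

## Reference experiment scale

The default configuration is 60 spectra per group (240 total), a 50/10
per-group training/validation split seeded alongside the simulation, PCA
to 95% variance, and the four adjacent/clinically relevant pairs
(control–mild, mild–moderate, moderate–reversal, mild–reversal).  The
whole experiment — simulation, 240 five-band fits, classification and
statistics — runs in a few seconds on one CPU, so tests and the
acceptance script use it at full scale.

## Known limitations

- The extinction curves are stylized; only their isosbestic structure and
  ordering ε(570) > ε(500) are load-bearing.
- The hemoglobin index has no absolute scale; only orderings and
  differences are meaningful.
- The fitted FAD center retains a small residual bias (≲ 0.2 nm at
  default concentrations) from the unmodeled absorption dip; it is
  documented rather than corrected, since the measured-data analysis this
  mirrors has the same property.
- Pairwise classifiers assume exactly two classes with a shared
  within-class covariance structure; no cross-validation beyond the
  single seeded split is provided.
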