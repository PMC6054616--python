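"""Grid resampling, 500 +/- 10 nm peak normalization, group averaging."""

from __future__ import annotations

import numpy as np

from .spectra_io import (
    LabeledSpectraSet,
    NormalizedSpectrum,
    Spectrum,
    SpectrumError,
)

#: Normalization window: closed interval around the 500 nm FAD peak.
NORM_WINDOW = (490.0, 510.0)


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spectrum.wavelengths[0] or grid[-1] > spectrum.wavelengths[-1]:
        raise SpectrumError(
            f"{spectrum.spectrum_id}: grid [{grid[0]}, {grid[-1]}] extends "
            f"beyond the measured span [{spectrum.wavelengths[0]}, "
            f"{spectrum.wavelengths[-1]}]"
        )
    if grid.shape == spectrum.wavelengths.shape and np.array_equal(
        grid, spectrum.wavelengths
    ):
        return spectrum
    intensities = np.interp(grid, spectrum.wavelengths, spectrum.intensities)
    return spectrum.copy_with(wavelengths=grid, intensities=intensities)


def normalize_500(spectrum: Spectrum) -> NormalizedSpectrum:
    """Scale a spectrum by its maximum intensity within 500 +/- 10 nm.

    The window maximum (not the global maximum) becomes exactly 1; the
    original window maximum is kept as ``normalization_factor``.
    Normalizing an already-normalized spectrum is a no-op (factor 1).
    """
    lo, hi = NORM_WINDOW
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise SpectrumError(
            f"{spectrum.spectrum_id}: no samples in the [{lo}, {hi}] nm window"
        )
    factor = float(spectrum.intensities[mask].max())
    if not factor > 0:
        raise SpectrumError(
            f"{spectrum.spectrum_id}: nonpositive maximum in the "
            f"normalization window (degenerate spectrum)"
        )
    return NormalizedSpectrum(
        spectrum_id=spectrum.spectrum_id,
        wavelengths=spectrum.wavelengths,
        intensities=spectrum.intensities / factor,
        group=spectrum.group,
        animal_id=spectrum.animal_id,
        normalization_factor=factor,
    )


def normalize_dataset(dataset: LabeledSpectraSet) -> LabeledSpectraSet:
    """Apply :func:`normalize_500` to every member spectrum."""
    return LabeledSpectraSet(
        [normalize_500(s) for s in dataset], grid=dataset.grid
    )


def average_group(dataset: LabeledSpectraSet, group: str) -> Spectrum:
    """Pointwise mean spectrum of one group on the common grid."""
    members = [s for s in dataset if s.group == group]
    if not members:
        raise SpectrumError(f"no spectra in group {group!r}")
    mean = np.mean([s.intensities for s in members], axis=0)
    return Spectrum(
        spectrum_id=f"{group}_mean",
        wavelengths=dataset.grid,
        intensities=mean,
        group=group,
    )
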