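"""Ratiometric total-hemoglobin index from spectral filtering modulation.

Hemoglobin along the photon path reshapes the emission spectrum.  Because
oxy- and deoxy-hemoglobin extinction coefficients are equal at 500 and
570 nm (isosbestic points), the ratio I(500)/I(570) depends on total
hemoglobin concentration but not on oxygen saturation.  The index
reported here is ln(I500/I570), which under Beer-Lambert attenuation is
exactly linear in concentration:

    ln(I500/I570) = ln(S0_500/S0_570) + c L (eps(570) - eps(500))

with S0 the hemoglobin-free emission.  Larger index = more hemoglobin.
The raw ratio is also emitted for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .spectra_io import LabeledSpectraSet, Spectrum, SpectrumError

WAVELENGTH_BLUE = 500.0
WAVELENGTH_GREEN = 570.0


@dataclass
class THCIndex:
    """Total-hemoglobin-concentration index of one spectrum."""

    value: float  # ln(i500 / i570)
    i500: float
    i570: float
    spectrum_id: str = ""
    group: str | None = None

    @property
    def ratio(self) -> float:
        return self.i500 / self.i570


def _intensity_at(spectrum: Spectrum, wavelength: float) -> float:
    idx = int(np.argmin(np.abs(spectrum.wavelengths - wavelength)))
    if abs(spectrum.wavelengths[idx] - wavelength) > 1e-6:
        raise SpectrumError(
            f"{spectrum.spectrum_id}: grid has no sample at {wavelength} nm"
        )
    return float(spectrum.intensities[idx])


def thc_index(spectrum: Spectrum) -> THCIndex:
    """Compute ln(I(500)/I(570)) for one spectrum on the standard grid."""
    i500 = _intensity_at(spectrum, WAVELENGTH_BLUE)
    i570 = _intensity_at(spectrum, WAVELENGTH_GREEN)
    if i500 <= 0 or i570 <= 0:
        raise SpectrumError(
            f"{spectrum.spectrum_id}: nonpositive intensity at 500/570 nm "
            f"(I500={i500}, I570={i570})"
        )
    return THCIndex(
        value=math.log(i500 / i570),
        i500=i500,
        i570=i570,
        spectrum_id=spectrum.spectrum_id,
        group=spectrum.group,
    )


def thc_table(dataset: LabeledSpectraSet) -> pd.DataFrame:
    """Per-spectrum hemoglobin indices as a tidy table."""
    rows = []
    for s in dataset:
        t = thc_index(s)
        rows.append(
            {
                "spectrum_id": t.spectrum_id,
                "group": t.group,
                "animal_id": s.animal_id,
                "i500": t.i500,
                "i570": t.i570,
                "ratio": t.ratio,
                "log_ratio": t.value,
            }
        )
    return pd.DataFrame(rows)


def thc_group_summary(dataset: LabeledSpectraSet) -> pd.DataFrame:
    """Box-plot statistics of the index per group.

    Median, 25th/75th percentiles (linear interpolation) and extremes —
    the five numbers a Box-and-Whisker plot displays.
    """
    table = thc_table(dataset)
    if table["group"].isna().any():
        raise SpectrumError("all spectra must carry a group label")
    rows = []
    for group, sub in table.groupby("group", sort=False):
        values = sub["log_ratio"].to_numpy()
        rows.append(
            {
                "group": group,
                "n": values.size,
                "median": float(np.median(values)),
                "q25": float(np.percentile(values, 25)),
                "q75": float(np.percentile(values, 75)),
                "min": float(values.min()),
                "max": float(values.max()),
            }
        )
    return pd.DataFrame(rows)
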