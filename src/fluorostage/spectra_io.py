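"""Spectrum containers and plain-CSV input/output.

A spectrum is one fluorescence emission trace: intensity (arbitrary units)
on a wavelength grid in nm, tagged with a lesion-group label.  Spectra are
exchanged as two-column CSV files (``wavelength_nm,intensity``) plus a
dataset manifest CSV (``spectrum_id,group,animal_id,file``); results are
written as ordinary CSV tables and a JSON run summary.  Intensities are
written at full double precision so that write-then-read round-trips are
bit exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The four lesion groups in increasing treatment-history order.
GROUPS = ("control", "mild", "moderate", "reversal")

#: Common emission grid: 441-750 nm inclusive at 1 nm, i.e. 310 samples
#: spanning the 440-750 nm emission window under 410 nm excitation.
STANDARD_GRID = np.arange(441.0, 751.0)


class SpectrumError(ValueError):
    """Raised for malformed spectra or manifests."""


@dataclass
class Spectrum:
    """One emission trace on a wavelength grid with identity metadata."""

    spectrum_id: str
    wavelengths: np.ndarray
    intensities: np.ndarray
    group: str | None = None
    animal_id: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise SpectrumError(
                f"{self.spectrum_id}: wavelength and intensity vectors differ "
                f"in length ({self.wavelengths.size} vs {self.intensities.size})"
            )
        if self.wavelengths.size < 2:
            raise SpectrumError(f"{self.spectrum_id}: need at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumError(
                f"{self.spectrum_id}: wavelengths must be strictly increasing"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError(f"{self.spectrum_id}: non-finite intensity values")
        if self.group is not None and self.group not in GROUPS:
            raise SpectrumError(
                f"{self.spectrum_id}: unknown group {self.group!r}; "
                f"expected one of {GROUPS} or None"
            )

    def __len__(self) -> int:
        return self.wavelengths.size

    def copy_with(self, **changes) -> "Spectrum":
        return replace(self, **changes)


@dataclass
class NormalizedSpectrum(Spectrum):
    """A spectrum scaled so its 500 +/- 10 nm window maximum is 1.

    ``normalization_factor`` is the original window maximum, kept so the
    raw trace can be restored and so chi-square values are comparable.
    """

    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.normalization_factor > 0:
            raise SpectrumError(
                f"{self.spectrum_id}: normalization factor must be positive"
            )


@dataclass
class LabeledSpectraSet:
    """Spectra sharing one wavelength grid, with group bookkeeping."""

    spectra: list[Spectrum]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumError("empty spectra set")
        if self.grid is None:
            self.grid = self.spectra[0].wavelengths
        self.grid = np.asarray(self.grid, dtype=float)
        for s in self.spectra:
            if s.wavelengths.shape != self.grid.shape or not np.array_equal(
                s.wavelengths, self.grid
            ):
                raise SpectrumError(
                    f"{s.spectrum_id}: not on the common grid; resample first"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spectra:
            key = s.group if s.group is not None else "unlabeled"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def subset(self, groups: Iterable[str]) -> "LabeledSpectraSet":
        wanted = set(groups)
        members = [s for s in self.spectra if s.group in wanted]
        if not members:
            raise SpectrumError(f"no spectra in groups {sorted(wanted)}")
        return LabeledSpectraSet(members, grid=self.grid)

    def intensity_matrix(self) -> np.ndarray:
        """Spectra stacked row-wise: shape (n_spectra, n_wavelengths)."""
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.spectra], dtype=object)


def read_spectrum(
    path: str | os.PathLike,
    spectrum_id: str | None = None,
    group: str | None = None,
    animal_id: str | None = None,
) -> Spectrum:
    """Read a two-column (wavelength_nm, intensity) CSV file.

    A single header line is tolerated.  Rows are sorted ascending in
    wavelength; duplicate wavelengths and negative intensities are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected two columns")
            try:
                wl, inten = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            rows.append((wl, inten))
    if not rows:
        raise SpectrumError(f"{path}: no data rows")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise SpectrumError(f"{path}: duplicate wavelengths")
    if np.any(arr[:, 1] < 0):
        raise SpectrumError(f"{path}: negative intensities")
    return Spectrum(
        spectrum_id=spectrum_id or path.stem,
        wavelengths=arr[:, 0],
        intensities=arr[:, 1],
        group=group,
        animal_id=animal_id,
    )


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column CSV at full double precision."""
    with open(path, "w") as fh:
        fh.write("wavelength_nm,intensity\n")
        for wl, inten in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(wl)!r},{float(inten)!r}\n")


MANIFEST_COLUMNS = ("spectrum_id", "group", "animal_id", "file")


def read_dataset(manifest: str | os.PathLike) -> LabeledSpectraSet:
    """Load all spectra listed in a manifest CSV.

    The manifest needs columns ``spectrum_id,group,animal_id,file``; file
    paths are resolved relative to the manifest.  Group labels must be one
    of the four lesion groups or empty (unlabeled, for prediction-only
    sets).  Spectra list order equals manifest row order.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise SpectrumError(f"{manifest}: missing manifest columns {missing}")
    spectra = []
    for idx, row in table.iterrows():
        group = row["group"] or None
        if group is not None and group not in GROUPS:
            raise SpectrumError(
                f"{manifest} row {idx}: unknown group {group!r}"
            )
        fpath = manifest.parent / row["file"]
        if not fpath.exists():
            raise SpectrumError(
                f"{manifest} row {idx} ({row['spectrum_id']}): "
                f"missing file {row['file']}"
            )
        spectra.append(
            read_spectrum(
                fpath,
                spectrum_id=row["spectrum_id"],
                group=group,
                animal_id=row["animal_id"] or None,
            )
        )
    return LabeledSpectraSet(spectra)


def write_dataset(dataset: LabeledSpectraSet, out_dir: str | os.PathLike) -> Path:
    """Write per-spectrum CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    rows = []
    for s in dataset:
        fname = f"spectra/{s.spectrum_id}.csv"
        write_spectrum(s, out_dir / fname)
        rows.append(
            {
                "spectrum_id": s.spectrum_id,
                "group": s.group or "",
                "animal_id": s.animal_id or "",
                "file": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write result tables as CSV plus a run_summary.json.

    ``tables`` maps a base name (e.g. ``"peaks"``) to a DataFrame; floats
    are written with shortest-round-trip precision so re-reading gives
    identical values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        written[name] = path
    summary_path = out_dir / "run_summary.json"
    summary = {"tables": sorted(tables.keys())}
    if config is not None:
        summary["config"] = dict(config)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    written["run_summary"] = summary_path
    return written
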