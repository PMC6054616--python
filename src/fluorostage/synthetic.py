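"""Forward simulation of liver autofluorescence spectra.

The model for a noiseless emission trace under 410 nm excitation is a sum
of Gaussian fluorophore bands attenuated by hemoglobin along the photon
path (Beer-Lambert with a fixed effective path)::

    S(lambda) = sum_k A_k exp(-(lambda - mu_k)^2 / (2 sigma_k^2))
                * exp(-c L (s eps_oxy(lambda) + (1-s) eps_deoxy(lambda)))

with ``c`` the dimensionless total-hemoglobin concentration, ``s`` the
oxygen saturation and ``L`` the effective path length.  Additive Gaussian
noise (sd a fixed fraction of the peak signal, clipped at zero) and a
per-animal log-normal amplitude factor emulate measurement noise and
animal-to-animal clustering of the twelve sites recorded per liver.

The extinction curves are smooth parametric stand-ins for oxy-/deoxy-
hemoglobin, constructed so 500 and 570 nm are exact isosbestic points:
ratio measurements at those two wavelengths are then independent of the
(unknown) oxygen saturation, which is what the 500/570 hemoglobin index
relies on.

Five fluorophore bands are simulated: NADH near 470 nm, FAD near 500 nm
(the dominant, normalization-defining band, whose center red-shifts with
fibrosis: 501 nm in controls, 505 nm in mild and 512 nm in moderate
fibrosis, returning to 502 nm on reversal), lipofuscin-like lipopigments
near 590 nm (amplitude growing with fibrosis), protoporphyrin IX near
630 nm, and a coproporphyrin band at 690 nm in controls/reversal that
sits blue-shifted at 670 nm in fibrotic livers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import GROUPS, LabeledSpectraSet, Spectrum, STANDARD_GRID

FLUOROPHORES = ("NADH", "FAD", "lipopigments", "porphyrin", "coproporphyrin")


def gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


@dataclass
class FluorophoreBand:
    """One Gaussian emission band: amplitude, center (nm), width sigma (nm)."""

    name: str
    center_mu: float
    width_sigma: float
    amplitude_A: float

    def __post_init__(self) -> None:
        if self.name not in FLUOROPHORES:
            raise ValueError(f"unknown fluorophore {self.name!r}")
        if not self.width_sigma > 0:
            raise ValueError(f"{self.name}: width_sigma must be positive")
        if self.amplitude_A < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude_A * gaussian(wavelengths, self.center_mu, self.width_sigma)


@dataclass
class ExtinctionModel:
    """Tabulated relative extinction of oxy- and deoxy-hemoglobin.

    Built by :func:`default_extinction_model` so that the two curves cross
    exactly at 500 and 570 nm (isosbestic points) with
    ``eps(570) > eps(500)``.
    """

    wavelengths: np.ndarray
    epsilon_oxy: np.ndarray
    epsilon_deoxy: np.ndarray

    def mixed(self, saturation: float) -> np.ndarray:
        """Saturation-weighted extinction s*eps_oxy + (1-s)*eps_deoxy."""
        return saturation * self.epsilon_oxy + (1.0 - saturation) * self.epsilon_deoxy

    def at(self, wavelength: float, saturation: float = 1.0) -> float:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.mixed(saturation)[idx])


def default_extinction_model(grid: np.ndarray = STANDARD_GRID) -> ExtinctionModel:
    """Parametric hemoglobin extinction curves on ``grid``.

    The oxygenated curve carries the two Q-band absorption peaks near 542
    and 577 nm; the deoxygenated curve a single broad peak near 555 nm.
    The deoxy curve is affinely rescaled so both curves agree exactly at
    500 and 570 nm, making those wavelengths isosbestic by construction.
    """
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() <= 500.0 and grid.max() >= 570.0):
        raise ValueError("grid must cover 500 and 570 nm")

    def raw_oxy(x):
        return 0.02 + 0.45 * gaussian(x, 542.0, 9.0) + gaussian(x, 577.0, 9.0)

    def raw_deoxy(x):
        return 0.02 + 1.05 * gaussian(x, 555.0, 13.0)

    # Affine map a*deoxy + b pinning the crossings at exactly 500 / 570 nm.
    o500, o570 = raw_oxy(500.0), raw_oxy(570.0)
    d500, d570 = raw_deoxy(500.0), raw_deoxy(570.0)
    a = (o570 - o500) / (d570 - d500)
    b = o500 - a * d500
    eps_oxy = raw_oxy(grid)
    eps_deoxy = a * raw_deoxy(grid) + b
    if np.any(eps_oxy < 0) or np.any(eps_deoxy < 0):
        raise ValueError("extinction curves must be nonnegative")
    return ExtinctionModel(grid, eps_oxy, eps_deoxy)


@dataclass
class GroupPreset:
    """Forward-model parameters for one fibrosis stage."""

    group: str
    bands: list[FluorophoreBand]
    hb_concentration_c: float = 0.0
    saturation_s: float = 0.75
    path_length_L: float = 1.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.hb_concentration_c < 0:
            raise ValueError("hb_concentration_c must be >= 0")
        if not 0.0 <= self.saturation_s <= 1.0:
            raise ValueError("saturation_s must lie in [0, 1]")
        if not self.path_length_L > 0:
            raise ValueError("path_length_L must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def band(self, name: str) -> FluorophoreBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def noiseless(
        self,
        grid: np.ndarray,
        extinction: ExtinctionModel | None = None,
        amplitude_factors: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Evaluate the noise-free forward model on ``grid``."""
        signal = np.zeros_like(np.asarray(grid, dtype=float))
        for b in self.bands:
            factor = 1.0 if amplitude_factors is None else amplitude_factors.get(b.name, 1.0)
            signal += factor * b.evaluate(grid)
        if self.hb_concentration_c > 0:
            if extinction is None:
                extinction = default_extinction_model(grid)
            attenuation = np.exp(
                -self.hb_concentration_c
                * self.path_length_L
                * extinction.mixed(self.saturation_s)
            )
            signal = signal * attenuation
        return signal


def _bands(spec: list[tuple[str, float, float, float]]) -> list[FluorophoreBand]:
    return [FluorophoreBand(n, mu, sig, amp) for n, mu, sig, amp in spec]


def default_presets() -> dict[str, GroupPreset]:
    """Stage presets encoding the group-dependent spectral signatures.

    FAD centers 501/505/512/502 nm for control/mild/moderate/reversal;
    lipopigment amplitude lowest in control and reversal, highest in
    moderate fibrosis; the coproporphyrin band at 690 nm in control and
    reversal but blue-shifted to 670 nm in fibrotic groups; hemoglobin
    concentration ordered moderate < mild < reversal < control.
    """
    return {
        "control": GroupPreset(
            group="control",
            bands=_bands(
                [
                    ("NADH", 470.0, 11.0, 0.55),
                    ("FAD", 501.0, 16.0, 1.00),
                    ("lipopigments", 590.0, 12.0, 0.10),
                    ("porphyrin", 630.0, 8.0, 0.06),
                    ("coproporphyrin", 690.0, 8.0, 0.05),
                ]
            ),
            hb_concentration_c=0.30,
        ),
        "mild": GroupPreset(
            group="mild",
            bands=_bands(
                [
                    ("NADH", 470.0, 11.0, 0.50),
                    ("FAD", 505.0, 16.0, 1.00),
                    ("lipopigments", 590.0, 12.0, 0.18),
                    ("porphyrin", 630.0, 8.0, 0.12),
                    ("coproporphyrin", 670.0, 8.0, 0.10),
                ]
            ),
            hb_concentration_c=0.12,
        ),
        "moderate": GroupPreset(
            group="moderate",
            bands=_bands(
                [
                    ("NADH", 470.0, 11.0, 0.45),
                    ("FAD", 512.0, 16.0, 1.00),
                    ("lipopigments", 590.0, 12.0, 0.30),
                    ("porphyrin", 630.0, 8.0, 0.16),
                    ("coproporphyrin", 670.0, 8.0, 0.14),
                ]
            ),
            hb_concentration_c=0.06,
        ),
        "reversal": GroupPreset(
            group="reversal",
            bands=_bands(
                [
                    ("NADH", 470.0, 11.0, 0.55),
                    ("FAD", 502.0, 16.0, 1.00),
                    ("lipopigments", 590.0, 12.0, 0.11),
                    ("porphyrin", 630.0, 8.0, 0.065),
                    ("coproporphyrin", 690.0, 8.0, 0.055),
                ]
            ),
            hb_concentration_c=0.21,
        ),
    }


def generate_spectrum(
    preset: GroupPreset,
    extinction: ExtinctionModel | None = None,
    rng_seed: int | np.random.Generator = 0,
    grid: np.ndarray = STANDARD_GRID,
    spectrum_id: str | None = None,
    animal_id: str | None = None,
    amplitude_factors: dict[str, float] | None = None,
) -> Spectrum:
    """Simulate one spectrum: forward model plus clipped Gaussian noise.

    Noise is i.i.d. zero-mean Gaussian with sd ``noise_sd`` times the peak
    of the noiseless signal, clipped at zero.  The same seed always yields
    the same spectrum.
    """
    grid = np.asarray(grid, dtype=float)
    if extinction is None:
        extinction = default_extinction_model(grid)
    signal = preset.noiseless(grid, extinction, amplitude_factors)
    if preset.noise_sd > 0:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        sd = preset.noise_sd * float(signal.max())
        signal = np.clip(signal + rng.normal(0.0, sd, size=grid.size), 0.0, None)
    return Spectrum(
        spectrum_id=spectrum_id or f"{preset.group}_sim",
        wavelengths=grid,
        intensities=signal,
        group=preset.group,
        animal_id=animal_id,
    )


#: Animals simulated per group (twelve measurement sites each at n=60).
N_ANIMALS_PER_GROUP = 5

#: Standard deviation of the per-animal log-normal amplitude factor.
ANIMAL_EFFECT_SD = 0.05


def generate_dataset(
    n_per_group: int = 60,
    seed: int = 17,
    presets: dict[str, GroupPreset] | None = None,
    extinction: ExtinctionModel | None = None,
    grid: np.ndarray = STANDARD_GRID,
    n_animals: int = N_ANIMALS_PER_GROUP,
    animal_effect_sd: float = ANIMAL_EFFECT_SD,
) -> LabeledSpectraSet:
    """Simulate ``n_per_group`` spectra for each of the four groups.

    Spectra are distributed round-robin over ``n_animals`` virtual animals
    per group; each animal carries a multiplicative log-normal amplitude
    factor per band (sd ``animal_effect_sd``) emulating the clustering of
    repeated sites within one liver.  The RNG stream is split per group /
    animal / spectrum by counter, so the dataset is reproducible from the
    seed for any ``n_per_group``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if presets is None:
        presets = default_presets()
    grid = np.asarray(grid, dtype=float)
    if extinction is None:
        extinction = default_extinction_model(grid)
    spectra: list[Spectrum] = []
    for gi, group in enumerate(GROUPS):
        preset = presets[group]
        band_names = [b.name for b in preset.bands]
        factors = {}
        for ai in range(n_animals):
            rng_a = np.random.default_rng([seed, gi, ai, 1])
            factors[ai] = {
                name: float(np.exp(rng_a.normal(0.0, animal_effect_sd)))
                for name in band_names
            }
        for si in range(n_per_group):
            ai = si % n_animals
            rng_s = np.random.default_rng([seed, gi, si, 2])
            spectra.append(
                generate_spectrum(
                    preset,
                    extinction,
                    rng_seed=rng_s,
                    grid=grid,
                    spectrum_id=f"{group}_a{ai:02d}_s{si:03d}",
                    animal_id=f"{group}_a{ai:02d}",
                    amplitude_factors=factors[ai],
                )
            )
    return LabeledSpectraSet(spectra, grid=grid)
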