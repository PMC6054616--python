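"""End-to-end orchestration: simulate -> preprocess -> fit -> classify -> stats.

The pipeline is pure with respect to (config, seed): running the same
configuration twice produces byte-identical tables.  Stage outputs are
files, so any stage can be re-entered from its predecessors' artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anova, classify, hemoglobin, peaks, preprocessing, spectra_io, synthetic

log = logging.getLogger("fluorostage")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults reproduce the reference experiment scale: 60 spectra per
    group (5 animals x 12 sites), 50 training and 10 validation spectra
    per group, PCA retained to 95% cumulative variance.
    """

    n_per_group: int = 60
    n_train: int = 50
    n_valid: int = 10
    seed: int = 17
    variance_threshold: float = 0.95
    fit_tol: float = 1e-8
    fit_max_iter: int = 500
    noise_sd: float | None = None  # None = preset default
    out_dir: str = "results"
    manifest: str | None = None  # use measured data instead of simulating
    preset_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_presets(config: RunConfig) -> dict[str, synthetic.GroupPreset]:
    presets = synthetic.default_presets()
    for group, overrides in config.preset_overrides.items():
        preset = presets[group]
        band_overrides = overrides.pop("bands", None)
        presets[group] = dataclasses.replace(preset, **overrides)
        if band_overrides:
            bands = []
            for b in presets[group].bands:
                changes = band_overrides.get(b.name, {})
                bands.append(dataclasses.replace(b, **changes))
            presets[group] = dataclasses.replace(presets[group], bands=bands)
    if config.noise_sd is not None:
        presets = {
            g: dataclasses.replace(p, noise_sd=config.noise_sd)
            for g, p in presets.items()
        }
    return presets


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order and write all result tables.

    On a stage failure the partial outputs are retained alongside a
    FAILED marker naming the stage, and the error is re-raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.manifest is not None:
            dataset = spectra_io.read_dataset(config.manifest)
        else:
            dataset = synthetic.generate_dataset(
                n_per_group=config.n_per_group,
                seed=config.seed,
                presets=_build_presets(config),
            )
        spectra_io.write_dataset(dataset, out_dir / "simulated")
        log.info("stage %s: %d spectra (%.2fs)", stage, len(dataset), time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        normalized = preprocessing.normalize_dataset(dataset)
        averages = {
            g: preprocessing.average_group(normalized, g)
            for g in spectra_io.GROUPS
            if g in normalized.group_counts
        }
        tables["group_averages"] = pd.DataFrame(
            {"wavelength_nm": normalized.grid}
            | {g: s.intensities for g, s in averages.items()}
        )
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "fit-peaks"
        t0 = time.perf_counter()
        tables["peaks"] = peaks.fit_dataset(
            normalized, max_iter=config.fit_max_iter, tol=config.fit_tol
        )
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "hemoglobin"
        t0 = time.perf_counter()
        tables["hemoglobin"] = hemoglobin.thc_table(normalized)
        tables["hemoglobin_summary"] = hemoglobin.thc_group_summary(normalized)
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        staging = classify.classify_dataset(
            normalized,
            n_train=config.n_train,
            n_valid=config.n_valid,
            seed=config.seed,
            variance_threshold=config.variance_threshold,
        )
        tables["classification"] = staging.report_table()
        roc_rows = []
        for pair, res in staging.pairs.items():
            for fpr, tpr in res.merged_roc_points:
                roc_rows.append(
                    {"pair": f"{pair[0]}-{pair[1]}", "fpr": fpr, "tpr": tpr}
                )
        tables["roc_points"] = pd.DataFrame(roc_rows)
        ell = staging.ellipse_summary
        tables["ellipses"] = pd.DataFrame(
            [
                {
                    "group": e.group,
                    "centroid_1": e.centroid[0],
                    "centroid_2": e.centroid[1],
                    "semi_axis_major": e.semi_axes[0],
                    "semi_axis_minor": e.semi_axes[1],
                    "n_inside": e.n_inside,
                    "n_outside": e.n_outside,
                }
                for e in ell.ellipses.values()
            ]
        )
        tables["confusion_matrix"] = ell.confusion_matrix.reset_index(names="true_group")
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        tables["anova"] = anova.pairwise_significance_table(
            tables["peaks"], tables["hemoglobin"]
        )
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)
    except Exception as exc:
        spectra_io.write_results(tables, out_dir, config.to_dict())
        (out_dir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
    return spectra_io.write_results(tables, out_dir, config.to_dict())
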