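"""One-way ANOVA over lesion groups for peak and hemoglobin variables.

Classical fixed-effects one-way ANOVA: F = MS_between / MS_within with
df_between = k - 1 and df_within = N - k, p from the F distribution.
Observations are treated as independent (the sixty spectra per group),
with the animal identifier preserved in the input tables so a clustered
analysis could be added later.  No multiple-testing correction is
applied; significance is flagged at both 0.05 and 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Adjacent-stage pairs examined for significance.
DEFAULT_PAIRS = (
    ("control", "mild"),
    ("mild", "moderate"),
    ("moderate", "reversal"),
)


@dataclass
class AnovaResult:
    variable: str
    groups_compared: tuple[str, ...]
    F: float
    df_between: int
    df_within: int
    p_value: float
    zero_within_variance: bool = False

    @property
    def significant_005(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_0005(self) -> bool:
        return self.p_value < 0.005


def one_way_anova(
    samples: list[np.ndarray],
    variable: str = "",
    groups: tuple[str, ...] | None = None,
) -> AnovaResult:
    """Classical one-way ANOVA across ``samples`` (one vector per group)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    for i, s in enumerate(samples):
        if s.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
    n_total = sum(s.size for s in samples)
    k = len(samples)
    grand_mean = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand_mean) ** 2 for s in samples)
    ss_within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    df_between = k - 1
    df_within = n_total - k
    zero_within = ss_within == 0.0
    if zero_within:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0  # all observations identical
        else:
            f_stat, p = np.inf, 0.0  # perfectly separated means
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        variable=variable,
        groups_compared=groups or tuple(f"group{i}" for i in range(k)),
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        zero_within_variance=zero_within,
    )


def _collect_variables(
    peaks_table: pd.DataFrame | None, hemoglobin_table: pd.DataFrame | None
) -> dict[str, pd.DataFrame]:
    """Map variable name -> DataFrame with columns (group, value)."""
    variables: dict[str, pd.DataFrame] = {}
    if peaks_table is not None:
        required = {"group", "band", "amplitude", "area"}
        missing = required - set(peaks_table.columns)
        if missing:
            raise ValueError(f"peaks table missing columns {sorted(missing)}")
        for band, sub in peaks_table.groupby("band", sort=False):
            variables[f"{band}_intensity"] = sub.rename(
                columns={"amplitude": "value"}
            )[["group", "value"]]
            variables[f"{band}_area"] = sub.rename(columns={"area": "value"})[
                ["group", "value"]
            ]
    if hemoglobin_table is not None:
        if "log_ratio" not in hemoglobin_table.columns:
            raise ValueError("hemoglobin table missing column 'log_ratio'")
        variables["thc_index"] = hemoglobin_table.rename(
            columns={"log_ratio": "value"}
        )[["group", "value"]]
    if not variables:
        raise ValueError("no input tables given")
    return variables


def pairwise_significance_table(
    peaks_table: pd.DataFrame | None = None,
    hemoglobin_table: pd.DataFrame | None = None,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Pairwise ANOVA per variable (band intensity/area, THC index) x pair.

    Output has one row per variable-pair combination with F, dfs, p and
    both significance flags.
    """
    variables = _collect_variables(peaks_table, hemoglobin_table)
    rows = []
    for name, table in variables.items():
        for pair in pairs:
            samples = [
                table.loc[table["group"] == g, "value"].to_numpy() for g in pair
            ]
            if any(s.size < 2 for s in samples):
                raise ValueError(f"pair {pair}: missing group data for {name}")
            res = one_way_anova(samples, variable=name, groups=pair)
            rows.append(
                {
                    "variable": name,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p_value": res.p_value,
                    "significant_0.05": res.significant_005,
                    "significant_0.005": res.significant_0005,
                }
            )
    return pd.DataFrame(rows)
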