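"""Compartment-resolved strain/displacement statistics and group tests.

Per-pixel strain and displacement maps are combined with compartment
labels to produce per-region summaries: the *absolute* hydrostatic strain
(mean of |eps|, extension and compression add up) and the *total*
hydrostatic strain (signed mean, extension and compression cancel), plus
shear and displacement magnitudes.  Group comparisons across compartments
use one-way ANOVA with Tukey HSD post-hoc tests and a two-tailed t-test
for the light-vs-dense binned comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .compartments import CompartmentLabels

DENSITY_REGIONS = tuple(f"C{i}" for i in range(1, 8))
SHELL_REGIONS = ("NLL", "PC1", "PC2", "PC3", "NUC")


def _region_mean(value_map: np.ndarray, mask: np.ndarray,
                 absolute: bool) -> float:
    vals = value_map[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan
    return float(np.abs(vals).mean() if absolute else vals.mean())


def compartment_strain_stats(strain_map: np.ndarray,
                             labels: CompartmentLabels,
                             mode: str = "absolute",
                             regions: Sequence[str] = DENSITY_REGIONS + ("NLL",)
                             ) -> pd.Series:
    """Mean hydrostatic strain per compartment at one frame.

    ``mode='absolute'`` averages |eps| (signs ignored); ``mode='total'``
    averages the signed strain so extension and compression can cancel.
    Empty compartments yield NaN.
    """
    if mode not in ("absolute", "total"):
        raise ValueError("mode must be 'absolute' or 'total'")
    out = {}
    for name in regions:
        try:
            mask = labels.region_mask(name)
        except KeyError:
            out[name] = np.nan
            continue
        out[name] = _region_mean(strain_map, mask, mode == "absolute")
    return pd.Series(out, name=f"{mode}_hydrostatic_strain")


def compartment_strain_table(hydro_map: np.ndarray, shear_map: np.ndarray,
                             displacement_map: np.ndarray,
                             labels: CompartmentLabels,
                             nucleus_id: int = 0,
                             regions: Sequence[str] = DENSITY_REGIONS + ("NLL",)
                             ) -> pd.DataFrame:
    """Full per-compartment summary at the peak-deformation frame.

    Columns: mean |eps_hydro| (absolute), signed mean eps_hydro (total),
    mean |eps_shear| and mean displacement magnitude (µm).  The invariant
    |total| <= absolute holds row-wise by the triangle inequality.
    """
    rows = []
    for name in regions:
        try:
            mask = labels.region_mask(name)
        except KeyError:
            mask = np.zeros_like(labels.interior_mask)
        rows.append({
            "nucleus": nucleus_id,
            "compartment": name,
            "n_pixels": int(mask.sum()),
            "abs_hydrostatic": _region_mean(hydro_map, mask, True),
            "total_hydrostatic": _region_mean(hydro_map, mask, False),
            "abs_shear": _region_mean(shear_map, mask, True),
            "mean_displacement_um": _region_mean(displacement_map, mask, True),
        })
    return pd.DataFrame(rows)


def shell_displacement_stats(displacement_map: np.ndarray,
                             labels: CompartmentLabels,
                             nucleus_id: int = 0) -> pd.DataFrame:
    """Mean displacement magnitude for NLL, PC1-PC3 shells and the whole
    nucleus interior (NUC)."""
    rows = []
    for name in SHELL_REGIONS:
        mask = labels.region_mask(name)
        rows.append({
            "nucleus": nucleus_id,
            "region": name,
            "n_pixels": int(mask.sum()),
            "mean_displacement_um": _region_mean(displacement_map, mask, True),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class BoxplotStats:
    """25-75 percentile box with whiskers excluding > 3 sigma outliers."""

    group: str
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int
    n_outliers: int


def boxplot_stats(values: np.ndarray, group: str = "",
                  outlier_k: float = 3.0) -> BoxplotStats:
    """Boxplot summary; whiskers span the data excluding points more than
    ``outlier_k`` standard deviations from the group mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    mean, std = v.mean(), v.std()
    keep = v if std == 0 else v[np.abs(v - mean) <= outlier_k * std]
    return BoxplotStats(
        group=group, median=float(np.median(v)),
        q25=float(np.percentile(v, 25)), q75=float(np.percentile(v, 75)),
        whisker_low=float(keep.min()), whisker_high=float(keep.max()),
        n=int(v.size), n_outliers=int(v.size - keep.size))


def group_tests(table: pd.DataFrame, value_col: str = "value",
                group_col: str = "group",
                binned_pair: Optional[tuple[Sequence[str], Sequence[str]]] = None
                ) -> dict:
    """One-way ANOVA + Tukey HSD across groups, optional binned t-test.

    ``binned_pair`` pools groups into two super-groups (e.g. light C1-C3
    vs dense C4-C7 chromatin) compared by a two-tailed unpaired t-test.
    Identical groups (zero between- and within-variance) report F=0, p=1.
    """
    groups = [g for _, g in table.groupby(group_col, sort=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g[value_col], dtype=float) for g in groups]
    names = sorted(table[group_col].unique())

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        anova = {"F": 0.0, "p": 1.0}
    else:
        F, p = sps.f_oneway(*arrays)
        anova = {"F": float(F), "p": float(p)}

    if np.ptp(pooled) == 0:
        tukey_frame = pd.DataFrame(
            [{"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0,
              "reject": False}
             for i, a in enumerate(names) for b in names[i + 1:]])
    else:
        res = pairwise_tukeyhsd(endog=table[value_col].to_numpy(dtype=float),
                                groups=table[group_col].to_numpy(),
                                alpha=0.05)
        tukey_frame = pd.DataFrame(
            res.summary().data[1:],
            columns=[c.replace("-", "_") for c in res.summary().data[0]])
        tukey_frame = tukey_frame.rename(columns={"p_adj": "p_adj"})

    report = {
        "anova": anova,
        "tukey": tukey_frame,
        "boxplots": [boxplot_stats(a, g) for a, g in zip(arrays, names)],
    }

    if binned_pair is not None:
        left, right = binned_pair
        lv = table.loc[table[group_col].isin(left), value_col].to_numpy(float)
        rv = table.loc[table[group_col].isin(right), value_col].to_numpy(float)
        if np.ptp(np.concatenate([lv, rv])) == 0:
            report["binned_ttest"] = {"t": 0.0, "p": 1.0}
        else:
            t, p = sps.ttest_ind(lv, rv)
            report["binned_ttest"] = {"t": float(t), "p": float(p)}
    return report
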