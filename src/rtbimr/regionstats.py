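"""Regional summaries and Sham-vs-rTBI group comparisons.

T2-weighted regional intensities are normalized to the mean
cerebrospinal-fluid signal of the ventricles; regional volumes are
voxel counts times the voxel volume; group comparisons use the
unpaired two-sided Student t-test (pooled variance) with means +- SD
and a direction-flagged fold change (larger group mean over smaller,
so folds read "x.x-fold lower/higher" and are always >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RegionMask:
    """Named boolean region with the acquisition's voxel volume."""

    name: str
    mask: np.ndarray
    voxel_volume_mm3: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel volume must be positive")


@dataclass
class GroupComparison:
    variable: str
    n_sham: int
    n_rtbi: int
    mean_sham: float
    sd_sham: float
    mean_rtbi: float
    sd_rtbi: float
    fold_change: float
    direction: str  # 'lower' / 'higher' / 'equal' in rTBI relative to Sham
    t: float
    p: float
    degenerate: bool = False


def normalize_t2(t2_image: np.ndarray, region: RegionMask,
                 csf_mask: RegionMask) -> float:
    """Regional mean T2-weighted intensity over the ventricular CSF mean."""
    t2_image = np.asarray(t2_image, dtype=float)
    if not csf_mask.mask.any():
        raise ValueError("empty CSF mask")
    if not region.mask.any():
        raise ValueError(f"empty region mask: {region.name}")
    csf_mean = float(t2_image[csf_mask.mask].mean())
    if csf_mean <= 0:
        raise ValueError("CSF mean intensity must be positive")
    return float(t2_image[region.mask].mean()) / csf_mean


def region_volume(mask: RegionMask) -> float:
    """Region volume in mm^3: voxel count times voxel volume."""
    return float(mask.mask.sum()) * mask.voxel_volume_mm3


def compare_groups(values_sham, values_rtbi, variable: str = "") -> GroupComparison:
    """Unpaired pooled-variance t-test plus fold change between groups."""
    xs = np.asarray(values_sham, dtype=float)
    xr = np.asarray(values_rtbi, dtype=float)
    xs = xs[np.isfinite(xs)]
    xr = xr[np.isfinite(xr)]
    if xs.size < 2 or xr.size < 2:
        raise ValueError("need at least 2 finite values per group")
    ms, mr = float(xs.mean()), float(xr.mean())
    ss, sr = float(xs.std(ddof=1)), float(xr.std(ddof=1))

    degenerate = ss == 0 and sr == 0
    if degenerate and ms == mr:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(xs, xr, equal_var=True)
        t, p = float(t), float(p)

    if mr == ms:
        fold, direction = 1.0, "equal"
    elif abs(mr) < abs(ms):
        fold, direction = _safe_fold(ms, mr), "lower"
    else:
        fold, direction = _safe_fold(mr, ms), "higher"
    return GroupComparison(variable, xs.size, xr.size, ms, ss, mr, sr,
                           fold, direction, t, p, degenerate=degenerate)


def _safe_fold(larger: float, smaller: float) -> float:
    return float("inf") if smaller == 0 else abs(larger) / abs(smaller)


def fold_change_2sf(mean_a: float, mean_b: float) -> float:
    """Direction-free fold change rounded to 2 significant figures.

    The study-report convention: larger mean over smaller, rounded the
    way the prose quotes folds ("1.6 fold lower").
    """
    if mean_a == mean_b:
        return 1.0
    hi, lo = max(abs(mean_a), abs(mean_b)), min(abs(mean_a), abs(mean_b))
    if lo == 0:
        return float("inf")
    fold = hi / lo
    from decimal import Decimal
    exponent = int(np.floor(np.log10(fold)))
    quant = Decimal(fold).scaleb(-exponent).quantize(Decimal("1.0"))
    return float(quant.scaleb(exponent))


def summarize_study(feature_table: pd.DataFrame) -> pd.DataFrame:
    """One group comparison per variable of a cohort feature table.

    Missing values are dropped per variable; a variable with fewer than
    two finite values in either group is reported absent (NaN row).
    """
    if "group" not in feature_table.columns:
        raise ValueError("feature table must carry a 'group' column")
    sham = feature_table[feature_table.group == "Sham"]
    rtbi = feature_table[feature_table.group == "rTBI"]
    rows = []
    for var in feature_table.columns:
        if var == "group":
            continue
        xs = sham[var].to_numpy(dtype=float)
        xr = rtbi[var].to_numpy(dtype=float)
        ns = int(np.isfinite(xs).sum())
        nr = int(np.isfinite(xr).sum())
        if ns < 2 or nr < 2:
            rows.append({"variable": var, "n_sham": ns, "n_rtbi": nr,
                         "mean_sham": np.nan, "sd_sham": np.nan,
                         "mean_rtbi": np.nan, "sd_rtbi": np.nan,
                         "fold_change": np.nan, "direction": "absent",
                         "t": np.nan, "p": np.nan, "degenerate": False})
            continue
        c = compare_groups(xs, xr, variable=var)
        rows.append(vars(c) | {"variable": var})
    return pd.DataFrame(rows).set_index("variable")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default report)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
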