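"""Quantification of hyperpolarized 13C chemical-shift-imaging data.

A 2D CSI acquisition yields one 13C spectrum per voxel on a coarse
spatial grid (16x16 in this study, 256 spectral points over a 5000 Hz
sweep). Metabolite signal is quantified as the area under the curve
(AUC) of each peak, normalized to the per-voxel noise level. Pyruvate
and lactate are then expressed as fractions of their sum (removing
polarization/delivery variation), urea is normalized to the total urea
signal in tissue surrounding the brain (a perfusion reference), and the
lactate-to-pyruvate ratio (Lac/Pyr) — the flux readout — is the ratio
of the two AUCs. Regional values are unweighted means over the voxels
carrying each anatomical label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CSI_REGIONS

METABOLITES = ("pyruvate", "lactate", "urea")

#: Voxels whose lactate+pyruvate AUC falls below this multiple of the
#: noise-equivalent AUC (the SD of a pure-noise integral over the same
#: windows, sigma * sqrt(spacing * width)) are excluded from regional means.
DEFAULT_SNR_THRESHOLD = 5.0

#: Points taken from each spectrum edge (both ends pooled) to estimate
#: the noise level when no explicit noise window is given.
DEFAULT_NOISE_POINTS = 32


@dataclass
class PeakWindow:
    """Integration window for one metabolite, in Hz."""

    metabolite: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"window for {self.metabolite}: low must be < high")

    def contains(self, axis: np.ndarray) -> np.ndarray:
        return (axis >= self.low) & (axis <= self.high)


def check_windows_disjoint(windows) -> None:
    """Raise if any two metabolite windows overlap."""
    ws = sorted(windows, key=lambda w: w.low)
    for a, b in zip(ws, ws[1:]):
        if b.low < a.high:
            raise ValueError(
                f"peak windows overlap: {a.metabolite} [{a.low}, {a.high}] and "
                f"{b.metabolite} [{b.low}, {b.high}]"
            )


@dataclass
class SpectralGrid:
    """Per-voxel 13C spectra on a spatial grid.

    ``spectra`` has shape (ny, nx, n_points) and holds the dynamic
    acquisition summed over time frames (AUC quantification is linear,
    so the sum carries the same information). ``region_labels`` assigns
    each voxel one of cortex / subcortex / surrounding / background.
    """

    spectra: np.ndarray
    freq_axis: np.ndarray
    region_labels: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.spectra.shape[-1] != self.freq_axis.size:
            raise ValueError("spectral dimension does not match frequency axis")
        if self.region_labels.shape != self.spectra.shape[:-1]:
            raise ValueError("region label map does not match grid shape")
        d = np.diff(self.freq_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("frequency axis must be strictly monotonic")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        bad = set(np.unique(self.region_labels)) - set(CSI_REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {bad}")


def compute_auc(spectrum: np.ndarray, window: PeakWindow, axis: np.ndarray,
                clamp: bool = True) -> float:
    """Trapezoidal peak area of ``spectrum`` over ``window`` (signal*Hz).

    Negative integrals (pure-noise windows) are clamped to 0 by default.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if window.low < axis.min() or window.high > axis.max():
        raise ValueError(
            f"window [{window.low}, {window.high}] outside axis range "
            f"[{axis.min()}, {axis.max()}]"
        )
    sel = window.contains(axis)
    auc = float(np.trapezoid(spectrum[sel], axis[sel]))
    if clamp:
        auc = max(auc, 0.0)
    return auc


def estimate_noise(spectrum: np.ndarray, noise_window: PeakWindow | None = None,
                   axis: np.ndarray | None = None,
                   n_edge_points: int = DEFAULT_NOISE_POINTS) -> float:
    """Noise level of a spectrum: SD over a signal-free window.

    With an explicit ``noise_window`` (and ``axis``) the SD is taken over
    that frequency range; otherwise over the outermost ``n_edge_points``
    of the spectrum (half from each end), which are signal-free for any
    sensible peak placement.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if noise_window is not None:
        if axis is None:
            raise ValueError("axis required with an explicit noise window")
        sel = noise_window.contains(np.asarray(axis, dtype=float))
        if sel.sum() < 2:
            raise ValueError("noise window selects fewer than 2 points")
        region = spectrum[sel]
    else:
        k = n_edge_points // 2
        if k < 1:
            raise ValueError("need at least 2 edge points for noise estimation")
        region = np.concatenate([spectrum[:k], spectrum[-k:]])
    return float(np.std(region))


def normalize_pyr_lac(auc_pyr: float, auc_lac: float) -> tuple[float, float]:
    """Fractional pyruvate and lactate: each divided by their sum.

    Removes global polarization/delivery scaling. Returns (nan, nan) when
    the voxel has no signal (sum == 0); callers flag such voxels excluded.
    """
    if auc_pyr < 0 or auc_lac < 0:
        raise ValueError("AUCs must be non-negative")
    total = auc_pyr + auc_lac
    if total == 0:
        return (float("nan"), float("nan"))
    return (auc_pyr / total, auc_lac / total)


def normalize_urea(auc_urea_voxel: float, surrounding_sum: float) -> float:
    """Urea AUC of a brain voxel over the summed surrounding-tissue urea."""
    if surrounding_sum <= 0:
        raise ValueError("surrounding urea sum must be positive")
    return auc_urea_voxel / surrounding_sum


@dataclass
class GridQuantification:
    """Per-voxel metrics plus regional means for one CSI grid."""

    voxel_table: pd.DataFrame
    regional_means: pd.DataFrame
    excluded: np.ndarray


def quantify_grid(grid: SpectralGrid, windows: dict[str, PeakWindow],
                  snr_threshold: float = DEFAULT_SNR_THRESHOLD,
                  n_noise_points: int = DEFAULT_NOISE_POINTS) -> GridQuantification:
    """Quantify every voxel of a CSI grid and summarize by region.

    Per voxel: noise level from the spectrum edges, metabolite AUCs
    divided by that noise, pyruvate/lactate fractions, urea normalized
    to the summed surrounding urea, and Lac/Pyr as the plain AUC ratio
    (the noise normalization cancels). Voxels whose lactate+pyruvate
    AUC falls below ``snr_threshold`` times the noise-equivalent AUC of
    the combined windows are excluded from the regional means. Regional means are unweighted; a region with no included
    voxel is reported absent (NaN).
    """
    missing = set(METABOLITES) - set(windows)
    if missing:
        raise ValueError(f"missing peak windows for: {sorted(missing)}")
    check_windows_disjoint(windows.values())

    ny, nx, _ = grid.spectra.shape
    axis = grid.freq_axis
    flat = grid.spectra.reshape(-1, axis.size)

    k = n_noise_points // 2
    edge = np.concatenate([flat[:, :k], flat[:, -k:]], axis=1)
    noise = edge.std(axis=1)
    noise = np.where(noise > 0, noise, np.nan)

    auc = {}
    for met in METABOLITES:
        w = windows[met]
        if w.low < axis.min() or w.high > axis.max():
            raise ValueError(f"{met} window outside the frequency axis")
        sel = w.contains(axis)
        raw = np.trapezoid(flat[:, sel], axis[sel], axis=1)
        auc[met] = np.clip(raw, 0.0, None)

    # noise-normalized AUCs (units: Hz, per noise SD)
    auc_n = {m: auc[m] / noise for m in METABOLITES}

    labels = grid.region_labels.reshape(-1)
    total = auc_n["pyruvate"] + auc_n["lactate"]
    # noise-equivalent AUC of the combined windows, in noise-SD units:
    # integrating pure noise over W Hz on an h-Hz grid has SD ~ sqrt(h*W)
    spacing = float(np.abs(np.diff(axis)).mean())
    combined_width = sum(windows[m].high - windows[m].low
                         for m in ("pyruvate", "lactate"))
    noise_equiv_auc = np.sqrt(spacing * combined_width)
    excluded = ~(total >= snr_threshold * noise_equiv_auc)  # NaN noise excludes

    with np.errstate(divide="ignore", invalid="ignore"):
        pyr_norm = np.where(total > 0, auc_n["pyruvate"] / total, np.nan)
        lac_norm = np.where(total > 0, auc_n["lactate"] / total, np.nan)
        lacpyr = np.where(auc_n["pyruvate"] > 0,
                          auc_n["lactate"] / auc_n["pyruvate"], np.nan)

    surround = labels == "surrounding"
    surrounding_sum = float(np.nansum(auc_n["urea"][surround]))
    if surrounding_sum > 0:
        urea_norm = auc_n["urea"] / surrounding_sum
    else:
        urea_norm = np.full(flat.shape[0], np.nan)

    iy, ix = np.divmod(np.arange(ny * nx), nx)
    voxel_table = pd.DataFrame({
        "y": iy, "x": ix, "region": labels,
        "noise": noise,
        "auc_pyr": auc_n["pyruvate"],
        "auc_lac": auc_n["lactate"],
        "auc_urea": auc_n["urea"],
        "pyr_norm": pyr_norm,
        "lac_norm": lac_norm,
        "urea_norm": urea_norm,
        "lacpyr": lacpyr,
        "excluded": excluded,
    })

    metrics = ["auc_pyr", "auc_lac", "auc_urea",
               "pyr_norm", "lac_norm", "urea_norm", "lacpyr"]
    rows = {}
    for region in ("cortex", "subcortex"):
        sub = voxel_table[(voxel_table.region == region) & ~voxel_table.excluded]
        if len(sub) == 0:
            rows[region] = {m: np.nan for m in metrics} | {"n_voxels": 0}
        else:
            rows[region] = {m: float(sub[m].mean()) for m in metrics}
            rows[region]["n_voxels"] = len(sub)
    regional = pd.DataFrame(rows).T
    regional.index.name = "region"

    return GridQuantification(voxel_table=voxel_table,
                              regional_means=regional,
                              excluded=excluded.reshape(ny, nx))


def interpolate_heatmap(metric_map: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling of a per-voxel metric map to image resolution.

    Source voxel centers map onto the target grid exactly (values at the
    corresponding target pixels equal the source values) and the output
    never leaves the [min, max] range of the input. Non-finite voxels
    propagate as masked (NaN) pixels.
    """
    metric_map = np.asarray(metric_map, dtype=float)
    ny, nx = metric_map.shape
    ty, tx = target_shape
    if ty < ny or tx < nx:
        raise ValueError("target resolution must be >= source resolution")
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)), metric_map, method="linear")
    yy = np.linspace(0, ny - 1, ty)
    xx = np.linspace(0, nx - 1, tx)
    pts = np.stack(np.meshgrid(yy, xx, indexing="ij"), axis=-1)
    return interp(pts.reshape(-1, 2)).reshape(ty, tx)
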