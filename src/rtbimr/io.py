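"""Reading and writing the pipeline's on-disk formats.

Feature tables travel as CSV (canonical variable headers plus
``subject_id`` and ``group``; missing cells empty). Images and stacks
use NIfTI via nibabel (inversion-recovery stacks put TI on the 4th
dimension, with a JSON sidecar listing the TIs in ms). CSI grids use an
NPZ multi-array container with named arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mrsi import SpectralGrid
from .relaxometry import InversionRecoverySeries


def save_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def load_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="subject_id")
    if "group" not in table.columns:
        raise ValueError("feature-table CSV must have a 'group' column")
    return table


def save_csi_grid(grid: SpectralGrid, path) -> None:
    np.savez(path, spectra=grid.spectra, freq_axis=grid.freq_axis,
             region_labels=grid.region_labels,
             truth=json.dumps(_jsonable(grid.truth)))


def load_csi_grid(path) -> SpectralGrid:
    with np.load(path, allow_pickle=False) as z:
        truth = json.loads(str(z["truth"])) if "truth" in z else {}
        return SpectralGrid(spectra=z["spectra"], freq_axis=z["freq_axis"],
                            region_labels=z["region_labels"], truth=truth)


def save_nifti(image: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_ir_stack(series: InversionRecoverySeries, stem) -> None:
    """Write a 4-D NIfTI (y, x, 1, TI), a mask NIfTI and a TI sidecar."""
    stem = Path(stem)
    save_nifti(series.signals[:, :, None, :], stem.with_suffix(".nii.gz"))
    save_nifti(series.brain_mask.astype(float), Path(str(stem) + "_mask.nii.gz"))
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump({"inversion_times_ms": list(series.ti_ms)}, fh)


def load_ir_stack(stem) -> InversionRecoverySeries:
    stem = Path(stem)
    signals = load_nifti(stem.with_suffix(".nii.gz"))
    if signals.ndim == 4:
        signals = signals[:, :, 0, :]
    mask = load_nifti(Path(str(stem) + "_mask.nii.gz")) > 0.5
    with open(stem.with_suffix(".json")) as fh:
        ti = json.load(fh)["inversion_times_ms"]
    return InversionRecoverySeries(ti_ms=np.asarray(ti, dtype=float),
                                   signals=signals, brain_mask=mask)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
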