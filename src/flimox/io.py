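"""Reading and writing the on-disk formats used by the pipeline.

TCSPC stacks are stored as multi-page TIFF (one page per time channel,
16-bit counts) with a YAML sidecar carrying the acquisition metadata
(``<stem>.yaml`` next to the TIFF).  Ground truth goes to a compressed
``.npz`` plus a per-mitochondrion CSV; Ct and read tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .decay import FitImage, TCSPCImage
from .synthetic import GroundTruth

__all__ = [
    "write_tcspc_tiff",
    "read_tcspc_tiff",
    "write_ground_truth",
    "read_ground_truth",
    "write_fit_image",
    "read_fit_image",
    "write_table",
    "read_table",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_tcspc_tiff(image: TCSPCImage, path) -> Path:
    """Write a photon-count stack as multi-page TIFF + YAML sidecar."""
    path = Path(path)
    if image.counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("photon counts exceed 16-bit TIFF range")
    pages = np.moveaxis(image.counts.astype(np.uint16), 2, 0)  # (C, H, W)
    tifffile.imwrite(path, pages)
    meta = {
        "n_channels": int(image.n_channels),
        "time_window_ns": float(image.time_window),
        "condition": image.condition,
        "imposed_pO2": None if image.imposed_po2 is None else float(image.imposed_po2),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_tcspc_tiff(path) -> TCSPCImage:
    """Read a stack written by :func:`write_tcspc_tiff`."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3:
        raise ValueError(f"{path} is not a multi-page TCSPC stack")
    counts = np.moveaxis(pages, 0, 2).astype(np.int32)
    with open(_sidecar_path(path)) as fh:
        meta = yaml.safe_load(fh)
    if int(meta["n_channels"]) != counts.shape[2]:
        raise ValueError("sidecar channel count disagrees with TIFF pages")
    return TCSPCImage(
        counts=counts,
        time_window=float(meta["time_window_ns"]),
        condition=str(meta.get("condition", "")),
        imposed_po2=meta.get("imposed_pO2"),
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Write truth arrays (.npz) and the per-mitochondrion pO2 table (.csv)."""
    path = Path(path)
    np.savez_compressed(
        path,
        mito_label_image=truth.mito_label_image,
        per_pixel_tau_mean=truth.per_pixel_tau_mean,
        per_pixel_params=truth.per_pixel_params,
    )
    table = pd.DataFrame(
        {"label": list(truth.per_mito_po2), "pO2_mmHg": list(truth.per_mito_po2.values())}
    )
    table.to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    table = pd.read_csv(path.with_suffix(".csv"))
    return GroundTruth(
        mito_label_image=arrays["mito_label_image"],
        per_mito_po2=dict(zip(table["label"].astype(int), table["pO2_mmHg"].astype(float))),
        per_pixel_tau_mean=arrays["per_pixel_tau_mean"],
        per_pixel_params=arrays["per_pixel_params"],
    )


_FIT_ARRAYS = ("tau1", "tau2", "a1", "a2", "tau_mean", "chi2_reduced",
               "photons", "mask", "chi2_flag")


def write_fit_image(fit: FitImage, path) -> Path:
    """Write per-pixel fit parameter maps as a compressed .npz."""
    path = Path(path)
    arrays = {name: getattr(fit, name) for name in _FIT_ARRAYS}
    np.savez_compressed(
        path, **arrays,
        condition=np.array(fit.condition),
        imposed_po2=np.array(np.nan if fit.imposed_po2 is None else fit.imposed_po2),
        spatial_binning=np.array(fit.spatial_binning),
    )
    return path


def read_fit_image(path) -> FitImage:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        arrays = {name: data[name] for name in _FIT_ARRAYS}
        condition = str(data["condition"])
        imposed = float(data["imposed_po2"])
        binning = int(data["spatial_binning"])
    return FitImage(**arrays, condition=condition,
                    imposed_po2=None if np.isnan(imposed) else imposed,
                    spatial_binning=binning)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a Ct / read-interval / result table as headered CSV."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
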