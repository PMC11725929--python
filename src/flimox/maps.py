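"""Figure-level metabolic readouts from fitted FLIM images.

Builds the quantities typically shown in FLIM oxygen-sensing figures:
normalized lifetime-distribution histograms, pseudocolor pO2/lifetime maps
(warm hues = short lifetime = low pO2 = high oxygen consumption), the
fractions of mitochondrial pixels in high-OCR (low-pO2) and low-OCR
(high-pO2) subpopulations, the FLIM-based redox ratio
FLIRR = a2%(NAD(P)H) / a1%(FAD), and the group-comparison statistics
(Mann-Whitney U, Welch t tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from matplotlib import colormaps
from scipy import stats

from .calibration import OxygenMap
from .decay import FitImage

__all__ = [
    "LifetimeHistogram",
    "SubpopulationSummary",
    "RedoxMap",
    "lifetime_histogram",
    "subpopulation_fractions",
    "reference_thresholds",
    "flirr_map",
    "mann_whitney",
    "unpaired_t_tests",
    "render_pseudocolor",
]


@dataclass
class LifetimeHistogram:
    """Normalized histogram of per-pixel mean lifetimes."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    condition: str = ""
    n_pixels: int = 0

    def mass_above(self, tau: float) -> float:
        """Fraction of histogram mass in bins entirely above ``tau``."""
        sel = self.bin_edges[:-1] >= tau
        return float(self.frequencies[sel].sum())


@dataclass
class SubpopulationSummary:
    """Fractions of valid pixels in the high-OCR (pO2 <= low threshold),
    low-OCR (pO2 >= high threshold) and intermediate subpopulations."""

    high_ocr_fraction: float
    low_ocr_fraction: float
    mid_fraction: float
    thresholds: tuple[float, float]
    condition: str = ""
    n_pixels: int = 0


@dataclass
class RedoxMap:
    """Per-pixel FLIRR = bound-NAD(P)H fraction / bound-FAD fraction."""

    flirr: np.ndarray
    mask: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.flirr[self.mask]


def lifetime_histogram(fit_image: FitImage, bin_width: float = 0.05,
                       restrict_to_mask: Optional[np.ndarray] = None
                       ) -> LifetimeHistogram:
    """Histogram of tau_mean over valid (optionally further masked) pixels.

    Bin edges are aligned to integer multiples of ``bin_width`` so halving
    the width refines the binning exactly.  Frequencies are normalized to
    sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel = fit_image.mask
    if restrict_to_mask is not None:
        sel = sel & (np.asarray(restrict_to_mask) > 0)
    values = fit_image.tau_mean[sel]
    if values.size == 0:
        raise ValueError("no valid pixels selected for the histogram")
    lo = np.floor(values.min() / bin_width)
    hi = np.ceil(values.max() / bin_width)
    if hi <= lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return LifetimeHistogram(bin_edges=edges,
                             frequencies=counts / counts.sum(),
                             condition=fit_image.condition,
                             n_pixels=int(values.size))


def reference_thresholds(reference_po2: np.ndarray,
                         percentiles: tuple[float, float] = (25.0, 75.0)
                         ) -> tuple[float, float]:
    """Subpopulation thresholds anchored to a reference pO2 distribution.

    Defaults to the 25th/75th percentiles of the pooled reference (e.g.
    wild-type) pixel distribution; absolute mmHg thresholds can always be
    passed directly instead.
    """
    values = np.asarray(reference_po2, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty reference distribution")
    lo, hi = np.percentile(values, percentiles)
    return float(lo), float(hi)


def subpopulation_fractions(oxygen_map: OxygenMap, low_thresh: float,
                            high_thresh: float) -> SubpopulationSummary:
    """Split valid pixels into high-OCR (pO2 <= low_thresh), low-OCR
    (pO2 >= high_thresh) and intermediate fractions.

    Oxygen tension correlates inversely with consumption: actively respiring
    mitochondria deplete their local O2.
    """
    if low_thresh >= high_thresh:
        raise ValueError("low_thresh must be below high_thresh")
    values = oxygen_map.valid_values
    if values.size == 0:
        raise ValueError("oxygen map has no valid pixels")
    high_ocr = float(np.mean(values <= low_thresh))
    low_ocr = float(np.mean(values >= high_thresh))
    return SubpopulationSummary(
        high_ocr_fraction=high_ocr,
        low_ocr_fraction=low_ocr,
        mid_fraction=1.0 - high_ocr - low_ocr,
        thresholds=(low_thresh, high_thresh),
        condition=oxygen_map.condition,
        n_pixels=int(values.size),
    )


def flirr_map(nadh_fit: FitImage, fad_fit: FitImage) -> RedoxMap:
    """FLIM redox ratio: bound NAD(P)H (a2%) over bound FAD (a1%), per pixel.

    The bound-cofactor amplitude fractions track OXPHOS versus glycolysis
    balance.  Images must be co-registered (identical shape); pixels invalid
    in either fit, or with zero FAD bound fraction, are masked.
    """
    if nadh_fit.tau_mean.shape != fad_fit.tau_mean.shape:
        raise ValueError("NAD(P)H and FAD images must have identical dimensions")
    mask = nadh_fit.mask & fad_fit.mask & (fad_fit.a1 > 0)
    flirr = np.full(nadh_fit.tau_mean.shape, np.nan)
    flirr[mask] = nadh_fit.a2[mask] / fad_fit.a1[mask]
    return RedoxMap(flirr=flirr, mask=mask)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test between two independent groups.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b <= 12) and tie-free, and the tie-corrected,
    continuity-corrected normal approximation otherwise.  Returns
    (U statistic of the first group, p-value).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def unpaired_t_tests(groups: pd.DataFrame,
                     pairs: Sequence[tuple[str, str]],
                     condition_col: str = "condition",
                     value_col: str = "value",
                     holm: bool = False) -> pd.DataFrame:
    """Welch unpaired t tests for the requested condition pairs.

    ``groups`` is a tidy table with a condition label and a value per row.
    No multiplicity correction is applied unless ``holm=True`` (Holm
    step-down on the requested family).
    """
    available = groups.groupby(condition_col)[value_col]
    by_label = {label: np.asarray(vals, dtype=float) for label, vals in available}
    rows = []
    for label_a, label_b in pairs:
        for label in (label_a, label_b):
            if label not in by_label:
                raise ValueError(f"unknown condition label: {label!r}")
            if by_label[label].size < 2:
                raise ValueError(f"condition {label!r} needs n >= 2")
        t, p = stats.ttest_ind(by_label[label_a], by_label[label_b], equal_var=False)
        rows.append({"pair": f"{label_a} vs {label_b}", "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    return out


def render_pseudocolor(source: OxygenMap | FitImage, path,
                       vmin: Optional[float] = None,
                       vmax: Optional[float] = None,
                       cmap: str = "RdYlBu") -> dict:
    """Write an 8-bit pseudocolor PNG; warm hues at low values, cool at high.

    Low pO2 (or short lifetime) renders warm (red/orange) and high pO2 (long
    lifetime) cool (blue), the orientation used for oxygen-map figures.
    Masked pixels are black.  Returns the colorbar metadata (limits, map).
    """
    if isinstance(source, OxygenMap):
        values, mask = source.po2, source.mask
    else:
        values, mask = source.tau_mean, source.mask
    if not mask.any():
        raise ValueError("nothing to render: empty mask")
    finite = values[mask]
    lo = float(finite.min()) if vmin is None else float(vmin)
    hi = float(finite.max()) if vmax is None else float(vmax)
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((values - lo) / span, 0.0, 1.0)
    rgba = colormaps[cmap](np.nan_to_num(norm, nan=0.0))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~mask] = 0
    PILImage.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return {"vmin": lo, "vmax": hi, "cmap": cmap, "path": str(path)}
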