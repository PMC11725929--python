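"""Myoglobin-FRET lifetime calibration and per-pixel pO2 back-calculation.

The mitochondria-targeted myoglobin-mCherry sensor reports local oxygen
through FRET: deoxygenated myoglobin quenches the mCherry donor, so the donor
lifetime rises hyperbolically with oxygen partial pressure,

    tau(pO2) = (tau_max - 0.914) * pO2 / (K + pO2) + 0.914        [ns]

where ``K`` (mmHg) is an affinity-like fitting constant, ``tau_max`` is the
lifetime at full oxygenation, and 0.914 ns is the deoxygenated asymptote of
the sensor.  The curve is anchored experimentally with rotenone-treated
cells: with complex I blocked the mitochondria consume no oxygen, so the
intracellular pO2 equals the media-imposed pO2 and the full-image averaged
lifetime at each imposed level gives one calibration point.  Inverting the
fitted curve converts any lifetime image into a pO2 map:

    pO2(tau) = K * (tau - 0.914) / (tau_max - tau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .decay import FitImage

__all__ = [
    "TAU_FLOOR",
    "CalibrationPoint",
    "CalibrationFit",
    "OxygenMap",
    "predict_lifetime",
    "calibration_tau",
    "fit_calibration",
    "backcalculate_po2",
    "po2_map",
]

#: Deoxygenated-asymptote lifetime of the sensor, ns.  Treated as a fixed
#: property of the probe, not refit per experiment.
TAU_FLOOR = 0.914


@dataclass
class CalibrationPoint:
    """One rotenone-reference observation: full-image averaged lifetime at an imposed pO2."""

    imposed_po2: float
    tau: float
    n_pixels: int = 0
    condition: str = "rotenone"

    def __post_init__(self) -> None:
        if self.imposed_po2 < 0:
            raise ValueError("imposed pO2 must be >= 0 mmHg")
        if self.tau <= 0:
            raise ValueError("lifetime must be positive")


@dataclass
class CalibrationFit:
    """Fitted hyperbola parameters (K, tau_max) with the floor held fixed."""

    K: float
    tau_max: float
    tau_floor: float = TAU_FLOOR
    rss: float = 0.0
    n_points: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.tau_max <= self.tau_floor:
            raise ValueError("tau_max must exceed the deoxygenated floor")
        if self.K <= 0:
            # a non-positive affinity constant means the optimizer ran off;
            # keep the object constructible but flag it
            self.converged = False


@dataclass
class OxygenMap:
    """Per-pixel pO2 (mmHg).  ``saturated_mask`` marks pixels whose lifetime
    reached or exceeded tau_max, where the inverted model diverges; they are
    excluded from ``mask``."""

    po2: np.ndarray
    mask: np.ndarray
    saturated_mask: np.ndarray
    condition: str = ""

    @property
    def valid_values(self) -> np.ndarray:
        return self.po2[self.mask]


def predict_lifetime(calib: CalibrationFit, po2) -> float | np.ndarray:
    """Sensor lifetime (ns) at oxygen partial pressure ``po2`` (mmHg).

    Strictly increasing in pO2; bounded in [tau_floor, tau_max).
    """
    po2_arr = np.asarray(po2, dtype=float)
    if np.any(po2_arr < 0):
        raise ValueError("pO2 must be >= 0 mmHg")
    tau = (calib.tau_max - calib.tau_floor) * po2_arr / (calib.K + po2_arr) + calib.tau_floor
    return float(tau) if tau.ndim == 0 else tau


def calibration_tau(fit_image: FitImage, bright_fraction: float = 0.75) -> CalibrationPoint:
    """Full-image averaged sensor lifetime for one calibration acquisition.

    Averages tau_mean over bright pixels only — those whose photon count
    reaches ``bright_fraction`` of the 95th percentile across valid pixels.
    Dim boundary pixels mix sensor signal with background and bias the
    average upward, so they are excluded from the calibration estimate.
    Requires the image to carry its imposed pO2.
    """
    if fit_image.imposed_po2 is None:
        raise ValueError("calibration image must carry an imposed pO2")
    if not fit_image.mask.any():
        raise ValueError("no valid pixels to average")
    photons = fit_image.photons[fit_image.mask]
    threshold = bright_fraction * np.percentile(photons, 95)
    sel = fit_image.mask & (fit_image.photons >= threshold)
    if not sel.any():
        sel = fit_image.mask
    return CalibrationPoint(
        imposed_po2=float(fit_image.imposed_po2),
        tau=float(np.nanmean(fit_image.tau_mean[sel])),
        n_pixels=int(sel.sum()),
        condition=fit_image.condition,
    )


def fit_calibration(points: Sequence[CalibrationPoint],
                    tau_floor: float = TAU_FLOOR) -> CalibrationFit:
    """Least-squares fit of (K, tau_max) to rotenone-reference points.

    Requires at least 3 points spanning at least 2 distinct imposed pO2
    levels.  Initialization: tau_max at the largest observed lifetime, K at
    the imposed level whose lifetime is closest to the half-saturation
    midpoint.
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    po2 = np.array([p.imposed_po2 for p in points], dtype=float)
    tau = np.array([p.tau for p in points], dtype=float)
    if np.unique(po2).size < 2:
        raise ValueError("calibration needs at least 2 distinct pO2 levels")

    tau_max0 = float(tau.max())
    if tau_max0 <= tau_floor:
        tau_max0 = tau_floor + 0.1
    midpoint = 0.5 * (tau_floor + tau_max0)
    k0 = float(po2[np.argmin(np.abs(tau - midpoint))])
    if k0 <= 0:
        k0 = max(float(np.median(po2[po2 > 0])) if np.any(po2 > 0) else 1.0, 1e-3)

    def model(p, K, tau_max):
        return (tau_max - tau_floor) * p / (K + p) + tau_floor

    converged = True
    try:
        popt, _ = curve_fit(
            model, po2, tau, p0=[k0, tau_max0],
            bounds=([1e-9, tau_floor + 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
        K_hat, tau_max_hat = float(popt[0]), float(popt[1])
    except RuntimeError:
        K_hat, tau_max_hat = k0, tau_max0
        converged = False

    rss = float(np.sum((model(po2, K_hat, tau_max_hat) - tau) ** 2))
    fit = CalibrationFit(K=K_hat, tau_max=tau_max_hat, tau_floor=tau_floor,
                         rss=rss, n_points=len(points))
    fit.converged = fit.converged and converged
    return fit


def backcalculate_po2(calib: CalibrationFit, tau) -> float | np.ndarray:
    """Invert the calibration: pO2 = K (tau - floor) / (tau_max - tau).

    Lifetimes at or below the floor map to 0 mmHg (fully deoxygenated);
    lifetimes at or above tau_max are saturated — the hyperbola has no finite
    pre-image there — and come back NaN (callers mask them).
    """
    tau_arr = np.asarray(tau, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        po2 = calib.K * (tau_arr - calib.tau_floor) / (calib.tau_max - tau_arr)
    po2 = np.where(tau_arr <= calib.tau_floor, 0.0, po2)
    po2 = np.where(tau_arr >= calib.tau_max, np.nan, po2)
    return float(po2) if po2.ndim == 0 else po2


def po2_map(fit_image: FitImage, calib: CalibrationFit) -> OxygenMap:
    """Back-calculate a per-pixel pO2 map from fitted mean lifetimes."""
    if not fit_image.mask.any():
        raise ValueError("fit image has no valid pixels to map")
    tau = fit_image.tau_mean
    po2 = np.full(tau.shape, np.nan)
    sel = fit_image.mask
    po2[sel] = backcalculate_po2(calib, tau[sel])
    saturated = fit_image.mask & np.asarray(tau >= calib.tau_max)
    mask = fit_image.mask & ~saturated
    return OxygenMap(po2=po2, mask=mask, saturated_mask=saturated,
                     condition=fit_image.condition)
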