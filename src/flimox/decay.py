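"""Per-pixel biexponential TCSPC decay fitting.

A TCSPC acquisition stores, for every pixel, a histogram of photon arrival
times across ``n_channels`` equal-width time channels spanning ``time_window``
nanoseconds.  The decay at each pixel is modelled as a sum of two
exponentials,

    m(t) = A1 * exp(-t / tau1) + A2 * exp(-t / tau2),

integrated over each time channel, and fitted by weighted nonlinear least
squares with Poisson weights ``1 / max(count, 1)``.  The amplitude-weighted
mean lifetime ``tau_mean = (a1*tau1 + a2*tau2) / (a1 + a2)`` (with
``a_i = A_i / (A1 + A2)``) is the primary readout; the amplitude fractions
``a1%``/``a2%`` act as free/bound population maps for NAD(P)H and FAD.

The fitter runs as a batched Levenberg-Marquardt over ``(log tau1, log tau2)``
with the two amplitudes solved in closed form at every step (variable
projection), which makes whole-image fits fast enough for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "TCSPCImage",
    "PixelFit",
    "FitImage",
    "amplitude_weighted_lifetime",
    "fit_pixel_decay",
    "fit_image",
    "bound_fraction_map",
]

#: Lifetimes are bounded below by this value (ns) during fitting.
TAU_LOWER_BOUND = 0.01

#: Relative tau1/tau2 separation below which the fit collapses to a single
#: exponential (the two components are not identifiable).
TAU_TIE_RTOL = 0.01


@dataclass
class TCSPCImage:
    """Photon-count stack: ``counts[row, col, channel]`` plus timing metadata.

    Parameters
    ----------
    counts
        Non-negative integer photon counts, shape ``(rows, cols, n_channels)``.
    time_window
        Total span of the arrival-time axis in nanoseconds.
    condition
        Free-text experimental condition label.
    imposed_po2
        Media-imposed oxygen partial pressure in mmHg, when the image belongs
        to a calibration (respiration-inhibited) series; ``None`` otherwise.
    """

    counts: np.ndarray
    time_window: float = 12.5
    condition: str = ""
    imposed_po2: Optional[float] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (rows, cols, channels) array")
        if self.counts.shape[2] < 2:
            raise ValueError("need at least 2 time channels")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def channel_width(self) -> float:
        """Width of one time channel in ns (time_window / n_channels)."""
        return self.time_window / self.n_channels

    def channel_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.time_window, self.n_channels + 1)


@dataclass
class PixelFit:
    """Biexponential fit result for a single pixel.

    ``tau1 <= tau2`` by convention; ``a1 + a2 == 1``; ``tau_mean`` is the
    amplitude-weighted mean lifetime.  ``valid`` is False when the pixel had
    too few photons or the optimizer failed.
    """

    tau1: float
    tau2: float
    a1: float
    a2: float
    tau_mean: float
    chi2_reduced: float
    photons: int
    valid: bool


@dataclass
class FitImage:
    """Per-pixel fit parameter maps with a validity mask.

    Arrays are 2-D (rows x cols); entries outside ``mask`` are NaN.
    ``chi2_flag`` marks fitted pixels whose reduced chi-square exceeds the
    quality threshold; they stay in ``mask`` by default.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    tau_mean: np.ndarray
    chi2_reduced: np.ndarray
    photons: np.ndarray
    mask: np.ndarray
    chi2_flag: np.ndarray
    condition: str = ""
    imposed_po2: Optional[float] = None
    spatial_binning: int = 1

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def amplitude_weighted_lifetime(a1: float, a2: float, tau1: float, tau2: float) -> float:
    """Amplitude-weighted mean lifetime ``(a1*tau1 + a2*tau2) / (a1 + a2)``.

    Raises
    ------
    ValueError
        If ``a1 + a2 == 0`` (undefined average) or a lifetime is non-positive.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    total = a1 + a2
    if np.any(total == 0):
        raise ValueError("amplitude sum must be positive")
    if np.any(np.asarray(tau1, dtype=float) <= 0) or np.any(np.asarray(tau2, dtype=float) <= 0):
        raise ValueError("lifetimes must be positive")
    out = (a1 * np.asarray(tau1, dtype=float) + a2 * np.asarray(tau2, dtype=float)) / total
    return float(out) if out.ndim == 0 else out


def _basis(tau: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Integral of exp(-t/tau) over each channel; tau (P,), edges (C+1,) -> (P, C)."""
    e = np.exp(-edges[None, :] / tau[:, None])
    return tau[:, None] * (e[:, :-1] - e[:, 1:])


def _basis_dtau(tau: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """d/dtau of the channel integral: e^{-a/tau}(1+a/tau) - e^{-b/tau}(1+b/tau)."""
    lo = edges[:-1][None, :]
    hi = edges[1:][None, :]
    t = tau[:, None]
    return np.exp(-lo / t) * (1.0 + lo / t) - np.exp(-hi / t) * (1.0 + hi / t)


def _solve_amplitudes(t1: np.ndarray, t2: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted 2x2 linear solve for non-negative amplitudes (variable projection)."""
    m11 = np.einsum("pc,pc,pc->p", w, t1, t1)
    m12 = np.einsum("pc,pc,pc->p", w, t1, t2)
    m22 = np.einsum("pc,pc,pc->p", w, t2, t2)
    b1 = np.einsum("pc,pc,pc->p", w, y, t1)
    b2 = np.einsum("pc,pc,pc->p", w, y, t2)
    det = m11 * m22 - m12 * m12
    # near-singular (tau1 ~ tau2): fall back to a single component
    tiny = det <= 1e-12 * np.maximum(m11 * m22, 1e-300)
    det_safe = np.where(tiny, 1.0, det)
    a1 = (m22 * b1 - m12 * b2) / det_safe
    a2 = (m11 * b2 - m12 * b1) / det_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        a1_only = np.where(m11 > 0, b1 / np.where(m11 > 0, m11, 1.0), 0.0)
        a2_only = np.where(m22 > 0, b2 / np.where(m22 > 0, m22, 1.0), 0.0)
    a1 = np.where(tiny, a1_only, a1)
    a2 = np.where(tiny, 0.0, a2)
    # clip negative amplitudes to the admissible boundary
    neg1 = a1 < 0
    neg2 = a2 < 0
    a1 = np.where(neg1, 0.0, a1)
    a2 = np.where(neg1, np.maximum(a2_only, 0.0), a2)
    a2 = np.where(neg2 & ~neg1, 0.0, a2)
    a1 = np.where(neg2 & ~neg1, np.maximum(a1_only, 0.0), a1)
    return a1, a2


def _weighted_logslope(y: np.ndarray, t: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Count-weighted slope of log(y) vs t over selected channels; (P,)."""
    w = np.where(sel[None, :], y, 0.0)
    logy = np.log(np.maximum(y, 0.5))
    sw = w.sum(axis=1)
    sw_safe = np.where(sw > 0, sw, 1.0)
    tx = np.broadcast_to(t[None, :], y.shape)
    mx = np.einsum("pc,pc->p", w, tx) / sw_safe
    my = np.einsum("pc,pc->p", w, logy) / sw_safe
    sxx = np.einsum("pc,pc->p", w, (tx - mx[:, None]) ** 2)
    sxy = np.einsum("pc,pc->p", w, (tx - mx[:, None]) * (logy - my[:, None]))
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    slope[sw == 0] = np.nan
    return slope


def _initial_taus(y: np.ndarray, t_mid: np.ndarray, window: float):
    """Head/tail log-linear starting values for (tau1, tau2)."""
    tail = t_mid > 0.35 * window
    head = t_mid < 0.15 * window
    s_tail = _weighted_logslope(y, t_mid, tail)
    s_head = _weighted_logslope(y, t_mid, head)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(s_tail < 0, -1.0 / np.where(s_tail < 0, s_tail, -1.0), np.nan)
        tau1 = np.where(s_head < 0, -1.0 / np.where(s_head < 0, s_head, -1.0), np.nan)
    tau2 = np.clip(np.nan_to_num(tau2, nan=0.25 * window), 0.05, 0.8 * window)
    tau1 = np.nan_to_num(tau1, nan=0.0)
    tau1 = np.where(tau1 <= 0, tau2 / 4.0, tau1)
    tau1 = np.clip(tau1, TAU_LOWER_BOUND, 0.8 * tau2)
    return tau1, tau2


def _lm_minimize(y: np.ndarray, w: np.ndarray, edges: np.ndarray,
                 th0: np.ndarray, max_iter: int, xtol: float):
    """Batched Levenberg-Marquardt over (log tau1, log tau2) with projected
    amplitudes (variable projection, exact Golub-Pereyra Jacobian including
    the amplitude response).  Each iteration touches only pixels that have
    not yet converged."""
    n_pix = y.shape[0]
    lo, hi = np.log(TAU_LOWER_BOUND), np.log(float(edges[-1]))
    th = np.clip(th0.copy(), lo, hi)

    def evaluate(theta, yy, ww):
        tt1 = np.exp(theta[:, 0])
        tt2 = np.exp(theta[:, 1])
        b1 = _basis(tt1, edges)
        b2 = _basis(tt2, edges)
        amp1, amp2 = _solve_amplitudes(b1, b2, yy, ww)
        resid = yy - amp1[:, None] * b1 - amp2[:, None] * b2
        cost = np.einsum("pc,pc,pc->p", ww, resid, resid)
        return cost, amp1, amp2, resid

    cost, amp1_all, amp2_all, _ = evaluate(th, y, w)
    lam = np.full(n_pix, 1e-3)
    active_idx = np.arange(n_pix)

    for _ in range(max_iter):
        if active_idx.size == 0:
            break
        th_a = th[active_idx]
        yy = y[active_idx]
        ww = w[active_idx]
        lam_a = lam[active_idx]
        tt1 = np.exp(th_a[:, 0])
        tt2 = np.exp(th_a[:, 1])
        t1b = _basis(tt1, edges)
        t2b = _basis(tt2, edges)
        amp1, amp2 = _solve_amplitudes(t1b, t2b, yy, ww)
        resid = yy - amp1[:, None] * t1b - amp2[:, None] * t2b
        # derivatives of the basis wrt log tau
        d1 = _basis_dtau(tt1, edges) * tt1[:, None]
        d2 = _basis_dtau(tt2, edges) * tt2[:, None]
        # normal matrix of the linear subproblem and its determinant
        m11 = np.einsum("pc,pc,pc->p", ww, t1b, t1b)
        m12 = np.einsum("pc,pc,pc->p", ww, t1b, t2b)
        m22 = np.einsum("pc,pc,pc->p", ww, t2b, t2b)
        mdet = m11 * m22 - m12 * m12
        mdet = np.where(np.abs(mdet) > 1e-300, mdet, 1e-300)

        def amp_response(di, col):
            # dA/dtheta from differentiating A = M^-1 b
            d_wy = np.einsum("pc,pc,pc->p", ww, di, yy)
            d_wt1 = np.einsum("pc,pc,pc->p", ww, di, t1b)
            d_wt2 = np.einsum("pc,pc,pc->p", ww, di, t2b)
            zero = np.zeros_like(d_wy)
            if col == 0:
                dm11, dm12, dm22 = 2 * d_wt1, d_wt2, zero
                db1, db2 = d_wy, zero
            else:
                dm11, dm12, dm22 = zero, d_wt1, 2 * d_wt2
                db1, db2 = zero, d_wy
            r1 = db1 - (dm11 * amp1 + dm12 * amp2)
            r2 = db2 - (dm12 * amp1 + dm22 * amp2)
            da1 = (m22 * r1 - m12 * r2) / mdet
            da2 = (m11 * r2 - m12 * r1) / mdet
            return da1, da2

        da1_1, da2_1 = amp_response(d1, 0)
        da1_2, da2_2 = amp_response(d2, 1)
        j1 = amp1[:, None] * d1 + da1_1[:, None] * t1b + da2_1[:, None] * t2b
        j2 = amp2[:, None] * d2 + da1_2[:, None] * t1b + da2_2[:, None] * t2b
        h11 = np.einsum("pc,pc,pc->p", ww, j1, j1)
        h12 = np.einsum("pc,pc,pc->p", ww, j1, j2)
        h22 = np.einsum("pc,pc,pc->p", ww, j2, j2)
        g1 = np.einsum("pc,pc,pc->p", ww, j1, resid)
        g2 = np.einsum("pc,pc,pc->p", ww, j2, resid)
        d11 = h11 * (1.0 + lam_a) + 1e-300
        d22 = h22 * (1.0 + lam_a) + 1e-300
        det = d11 * d22 - h12 * h12
        det = np.where(np.abs(det) > 1e-300, det, 1e-300)
        s1 = (d22 * g1 - h12 * g2) / det
        s2 = (d11 * g2 - h12 * g1) / det
        step = np.stack([s1, s2], axis=1)
        th_new = np.clip(th_a + step, lo, hi)
        cost_new, amp1_new, amp2_new, _ = evaluate(th_new, yy, ww)
        improved = cost_new <= cost[active_idx]
        upd = active_idx[improved]
        th[upd] = th_new[improved]
        cost[upd] = cost_new[improved]
        amp1_all[upd] = amp1_new[improved]
        amp2_all[upd] = amp2_new[improved]
        lam[upd] = np.maximum(lam[upd] / 3.0, 1e-12)
        rej = active_idx[~improved]
        lam[rej] = np.minimum(lam[rej] * 4.0, 1e8)
        small_step = np.max(np.abs(step), axis=1) < xtol
        done = (improved & small_step) | (lam[active_idx] >= 1e7)
        active_idx = active_idx[~done]

    return th, cost, amp1_all, amp2_all


def _batch_fit(y: np.ndarray, edges: np.ndarray, offset: float = 0.0,
               max_iter: int = 60, xtol: float = 1e-9,
               reweight_passes: int = 1):
    """Fit the biexponential model to P decay histograms simultaneously.

    Parameters
    ----------
    y : (P, C) float array of channel counts.
    edges : (C+1,) channel edges in ns.
    offset : fixed time offset of the excitation pulse (delta IRF), ns.
    reweight_passes : after the first minimization with observed-count
        weights ``1/max(y, 1)``, the weights are recomputed from the fitted
        model (``1/max(m, 1)``, Pearson style) and the fit repeated.
        Observed-count weighting is biased where expected counts are small
        (the decay tail); model-based reweighting removes most of that bias.

    Returns dict of (P,) arrays: tau1, tau2, a1, a2, amp1, amp2, chi2, ok.
    """
    y = np.asarray(y, dtype=float)
    n_pix, n_chan = y.shape
    if offset:
        edges = np.clip(edges - offset, 0.0, None)
    window = float(edges[-1])
    t_mid = 0.5 * (edges[:-1] + edges[1:])

    tau1, tau2 = _initial_taus(y, t_mid, window)
    th = np.stack([np.log(tau1), np.log(tau2)], axis=1)

    w = 1.0 / np.maximum(y, 1.0)
    th, cost, amp1, amp2 = _lm_minimize(y, w, edges, th, max_iter, xtol)
    for _ in range(reweight_passes):
        model = (amp1[:, None] * _basis(np.exp(th[:, 0]), edges)
                 + amp2[:, None] * _basis(np.exp(th[:, 1]), edges))
        w = 1.0 / np.maximum(model, 1.0)
        th, cost, amp1, amp2 = _lm_minimize(y, w, edges, th, max_iter, xtol)

    tau1 = np.exp(th[:, 0])
    tau2 = np.exp(th[:, 1])
    # order convention: tau1 <= tau2
    flip = tau1 > tau2
    tau1_o = np.where(flip, tau2, tau1)
    tau2_o = np.where(flip, tau1, tau2)
    amp1_o = np.where(flip, amp2, amp1)
    amp2_o = np.where(flip, amp1, amp2)
    tau1, tau2, amp1, amp2 = tau1_o, tau2_o, amp1_o, amp2_o

    total_amp = amp1 + amp2
    ok = total_amp > 0
    a1 = np.where(ok, amp1 / np.where(ok, total_amp, 1.0), np.nan)
    # unresolvable component pairs collapse to a single exponential
    tie = ok & (np.abs(tau2 - tau1) <= TAU_TIE_RTOL * tau2)
    mean_tau = np.where(ok, a1 * tau1 + (1 - a1) * tau2, np.nan)
    tau1 = np.where(tie, mean_tau, tau1)
    tau2 = np.where(tie, mean_tau, tau2)
    a1 = np.where(tie, 1.0, a1)
    # vanished components likewise are single exponentials
    only2 = ok & (a1 == 0.0)
    tau1 = np.where(only2, tau2, tau1)
    a1 = np.where(only2, 1.0, a1)
    tau2 = np.where(ok & (a1 == 1.0), tau1, tau2)

    chi2 = cost / max(n_chan - 4, 1)
    return {
        "tau1": tau1, "tau2": tau2, "a1": a1, "a2": 1.0 - a1,
        "amp1": amp1, "amp2": amp2, "chi2": chi2, "ok": ok,
    }


def fit_pixel_decay(histogram: np.ndarray, channel_width: float,
                    min_photons: int = 100, offset: float = 0.0) -> PixelFit:
    """Fit one pixel's decay histogram; see module docstring for the model.

    Pixels with fewer than ``min_photons`` total counts (or an all-zero
    histogram) come back with ``valid=False`` rather than raising.
    """
    histogram = np.asarray(histogram, dtype=float)
    if histogram.ndim != 1 or histogram.size < 8:
        raise ValueError("histogram must be 1-D with at least 8 channels")
    if channel_width <= 0:
        raise ValueError("channel_width must be positive")
    if np.any(histogram < 0):
        raise ValueError("negative counts are not a valid photon histogram")
    photons = int(round(histogram.sum()))
    if photons < max(min_photons, 1):
        return PixelFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, photons, False)
    edges = np.arange(histogram.size + 1) * channel_width
    res = _batch_fit(histogram[None, :], edges, offset=offset)
    ok = bool(res["ok"][0])
    if not ok:
        return PixelFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, photons, False)
    a1 = float(res["a1"][0])
    t1 = float(res["tau1"][0])
    t2 = float(res["tau2"][0])
    return PixelFit(
        tau1=t1, tau2=t2, a1=a1, a2=1.0 - a1,
        tau_mean=a1 * t1 + (1.0 - a1) * t2,
        chi2_reduced=float(res["chi2"][0]), photons=photons, valid=True,
    )


def fit_image(image: TCSPCImage, min_photons: int = 100,
              spatial_binning: int = 1, offset: float = 0.0,
              chi2_threshold: float = 5.0, channel_rebin: int = 1) -> FitImage:
    """Fit every pixel of a TCSPC image, optionally pooling neighborhoods.

    ``spatial_binning`` k > 1 sums photon histograms over a sliding k x k
    neighborhood before fitting (higher counts, lower spatial resolution) —
    the usual trade-off when per-pixel counts are low.  ``min_photons`` is a
    per-pixel budget: with binning the pooled threshold scales as
    ``min_photons * k**2``, so dim background does not pass the gate merely
    by being pooled.  Sub-threshold pixels are masked, not fitted.

    ``channel_rebin`` r > 1 merges r consecutive time channels before
    fitting (must divide the channel count).  For nanosecond-scale
    lifetimes sampled at ~50 ps, moderate rebinning loses essentially no
    information and cuts fit time proportionally.
    """
    rows, cols = image.shape
    if spatial_binning < 1:
        raise ValueError("spatial_binning must be >= 1")
    if spatial_binning > min(rows, cols):
        raise ValueError("spatial binning window exceeds image size")
    if channel_rebin < 1 or image.n_channels % channel_rebin:
        raise ValueError("channel_rebin must divide the channel count")
    counts = image.counts.astype(float)
    if spatial_binning > 1:
        k = spatial_binning
        counts = ndimage.uniform_filter(counts, size=(k, k, 1), mode="constant") * (k * k)
        counts = np.round(counts)
    n_channels = image.n_channels
    edges = image.channel_edges()
    if channel_rebin > 1:
        n_channels = image.n_channels // channel_rebin
        counts = counts.reshape(rows, cols, n_channels, channel_rebin).sum(axis=3)
        edges = edges[::channel_rebin]

    flat = counts.reshape(-1, n_channels)
    photons = flat.sum(axis=1)
    fit_sel = photons >= max(min_photons, 1) * spatial_binning ** 2

    shape = (rows, cols)
    out = {k: np.full(shape, np.nan) for k in
           ("tau1", "tau2", "a1", "a2", "tau_mean", "chi2")}
    mask = np.zeros(shape, dtype=bool)
    chi2_flag = np.zeros(shape, dtype=bool)

    if fit_sel.any():
        res = _batch_fit(flat[fit_sel], edges, offset=offset)
        ok = res["ok"]
        idx = np.flatnonzero(fit_sel)[ok]
        rr, cc = np.unravel_index(idx, shape)
        out["tau1"][rr, cc] = res["tau1"][ok]
        out["tau2"][rr, cc] = res["tau2"][ok]
        out["a1"][rr, cc] = res["a1"][ok]
        out["a2"][rr, cc] = res["a2"][ok]
        out["tau_mean"][rr, cc] = res["a1"][ok] * res["tau1"][ok] + res["a2"][ok] * res["tau2"][ok]
        out["chi2"][rr, cc] = res["chi2"][ok]
        mask[rr, cc] = True
        chi2_flag[rr, cc] = res["chi2"][ok] > chi2_threshold

    return FitImage(
        tau1=out["tau1"], tau2=out["tau2"], a1=out["a1"], a2=out["a2"],
        tau_mean=out["tau_mean"], chi2_reduced=out["chi2"],
        photons=photons.reshape(shape), mask=mask, chi2_flag=chi2_flag,
        condition=image.condition, imposed_po2=image.imposed_po2,
        spatial_binning=spatial_binning,
    )


def bound_fraction_map(fit: FitImage, component: str = "long") -> np.ndarray:
    """Amplitude-fraction map in percent for the short (a1%) or long (a2%) component.

    For NAD(P)H the short-lifetime component is conventionally the free
    cofactor and the long component the protein-bound one; for FAD the roles
    reverse.  Masked pixels are NaN.
    """
    if component not in ("short", "long"):
        raise ValueError("component must be 'short' or 'long'")
    frac = fit.a1 if component == "short" else fit.a2
    out = np.where(fit.mask, frac * 100.0, np.nan)
    return out
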