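"""Synthetic TCSPC scenes, calibration series, qPCR Ct tables and read pileups.

Every input the analysis pipeline consumes can be generated here with known
ground truth, which makes parameter-recovery testing possible without an
instrument.  The decay scene generator emulates a two-photon FLIM
acquisition of mitochondria expressing the myoglobin-mCherry oxygen sensor:

* mitochondria are non-overlapping disks on a dark background;
* each mitochondrion draws its pO2 from a two-component Gaussian mixture
  (a high-OCR / low-pO2 subpopulation and a low-OCR / high-pO2 one);
* pO2 sets the amplitude-weighted mean lifetime through the hyperbolic
  sensor model (see :mod:`flimox.calibration`); the decay at each pixel is
  biexponential with a fixed short (FRET-quenched) component and a long
  component positioned so that the amplitude-weighted mean equals the
  model lifetime;
* per-pixel photon totals are Poisson, and photons distribute over the
  256-channel / 12.5 ns arrival-time histogram multinomially with channel
  probabilities proportional to the channel-integrated biexponential
  (truncated at the window; a delta-function excitation pulse is assumed).

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import TAU_FLOOR, CalibrationFit, predict_lifetime
from .decay import TCSPCImage, _basis

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "CtSpec",
    "PlacementError",
    "WT_MIXTURE",
    "KO_MIXTURE",
    "generate_decay_image",
    "generate_calibration_series",
    "generate_ct_table",
    "generate_reads",
]

#: Default pO2 mixtures (weight, mean mmHg, sd mmHg).  The wild-type-like
#: population is dominated by actively respiring (high-OCR, low-pO2)
#: mitochondria; the knockout-like population by quiescent (low-OCR,
#: high-pO2) ones.
WT_MIXTURE = ((0.6, 10.0, 3.0), (0.4, 60.0, 10.0))
KO_MIXTURE = ((0.2, 10.0, 3.0), (0.8, 60.0, 10.0))


class PlacementError(RuntimeError):
    """Raised when non-overlapping mitochondria cannot be placed."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic FLIM acquisition.

    Acquisition geometry defaults follow a typical TCSPC setup: 256 x 256
    pixels, 256 time channels over a 12.5 ns window (80 MHz excitation).
    ``short_lifetime``/``short_fraction`` are the FRET-quenched biexponential
    component (tau1, a1); the long component is derived per mitochondrion
    from its pO2.  ``truth_K``/``truth_tau_max`` parameterize the forward
    sensor model.
    """

    image_height: int = 256
    image_width: int = 256
    n_channels: int = 256
    time_window: float = 12.5
    mito_count: int = 25
    mito_radius_range: tuple[float, float] = (2.0, 5.0)
    background_photon_rate: float = 20.0
    mito_photon_budget: float = 5000.0
    po2_mixture: Sequence[tuple[float, float, float]] = WT_MIXTURE
    truth_K: float = 15.0
    truth_tau_max: float = 2.5
    tau_floor: float = TAU_FLOOR
    short_lifetime: float = 0.6
    short_fraction: float = 0.3
    condition: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for w, _, _ in self.po2_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(m < 0 for _, m, _ in self.po2_mixture):
            raise ValueError("mixture pO2 means must be >= 0")
        if not (0 < self.short_lifetime < self.truth_tau_max):
            raise ValueError("short_lifetime must lie in (0, truth_tau_max)")
        if not (0 <= self.short_fraction <= 1):
            raise ValueError("short_fraction must lie in [0, 1]")
        if self.n_channels < 2:
            raise ValueError("need at least 2 time channels")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")
        if self.truth_tau_max <= self.tau_floor:
            raise ValueError("truth_tau_max must exceed tau_floor")
        if self.mito_radius_range[0] > self.mito_radius_range[1]:
            raise ValueError("invalid radius range")

    def truth_calibration(self) -> CalibrationFit:
        """The forward sensor model as a CalibrationFit (for round trips)."""
        return CalibrationFit(K=self.truth_K, tau_max=self.truth_tau_max,
                              tau_floor=self.tau_floor, n_points=0)


@dataclass
class GroundTruth:
    """Truth channel for a generated scene.

    ``mito_label_image`` assigns every pixel an integer mitochondrion label
    (0 = background).  ``per_mito_po2`` maps label -> drawn pO2 (mmHg).
    ``per_pixel_params`` stacks (tau1, tau2, a1, a2) along the last axis;
    background pixels are NaN.
    """

    mito_label_image: np.ndarray
    per_mito_po2: dict[int, float]
    per_pixel_tau_mean: np.ndarray
    per_pixel_params: np.ndarray

    def mito_mask(self) -> np.ndarray:
        return self.mito_label_image > 0


@dataclass
class CtSpec:
    """Spec for a synthetic qPCR plate.

    ``true_abundance`` maps (sample, target, role) -> template amount in
    arbitrary units for roles 'IP', 'input' and 'RNaseH-IP'; ``dilution``
    maps role -> fold dilution applied before the plate.  Ct values follow
    Ct = intercept - log_E(abundance / dilution) + N(0, replicate_sd), with
    amplification efficiency E per cycle.
    """

    true_abundance: Mapping[tuple[str, str, str], float]
    dilution: Mapping[str, float] = field(
        default_factory=lambda: {"IP": 10.0, "input": 100.0, "RNaseH-IP": 10.0})
    replicate_sd: float = 0.15
    efficiency: float = 2.0
    intercept: float = 30.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dilution.values()):
            raise ValueError("dilutions must be >= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")


def _place_disks(rng: np.random.Generator, spec: SceneSpec,
                 max_attempts_per_disk: int = 400):
    """Rejection-sample non-overlapping disk centers/radii."""
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    r_lo, r_hi = spec.mito_radius_range
    for _ in range(spec.mito_count):
        for attempt in range(max_attempts_per_disk):
            r = float(rng.uniform(r_lo, r_hi))
            cy = float(rng.uniform(r, spec.image_height - r))
            cx = float(rng.uniform(r, spec.image_width - r))
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 1.0) ** 2
                   for (y, x), rr in zip(centers, radii)):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {spec.mito_count} non-overlapping mitochondria "
                f"in a {spec.image_height}x{spec.image_width} field")
    return centers, radii


def _long_lifetime(spec: SceneSpec, tau_mean: np.ndarray) -> np.ndarray:
    """Long component tau2 that yields the requested amplitude-weighted mean
    given the fixed short component (tau1, a1)."""
    a1 = spec.short_fraction
    if a1 >= 1.0:
        return np.asarray(tau_mean, dtype=float)
    tau2 = (np.asarray(tau_mean, dtype=float) - a1 * spec.short_lifetime) / (1.0 - a1)
    if np.any(tau2 <= spec.short_lifetime):
        raise ValueError(
            "scene parameters give a long lifetime at or below the short one; "
            "lower short_lifetime or short_fraction")
    return tau2


def _sample_histograms(rng: np.random.Generator, n_photons: np.ndarray,
                       channel_p: np.ndarray) -> np.ndarray:
    """Multinomial photon histograms for pixels sharing channel probabilities."""
    return rng.multinomial(n_photons.astype(np.int64), channel_p)


def generate_decay_image(spec: SceneSpec,
                         po2_override: Optional[float] = None
                         ) -> tuple[TCSPCImage, GroundTruth]:
    """Generate one TCSPC image with ground truth.

    ``po2_override`` clamps every mitochondrion to a single pO2 level
    (the respiration-inhibited reference condition) instead of drawing from
    the mixture.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, c = spec.image_height, spec.image_width, spec.n_channels
    edges = np.linspace(0.0, spec.time_window, c + 1)

    centers, radii = _place_disks(rng, spec)
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i

    # per-mitochondrion pO2 from the mixture (or the imposed level)
    n_mito = len(centers)
    if po2_override is not None:
        po2_vals = np.full(n_mito, float(po2_override))
    else:
        weights = np.array([wgt for wgt, _, _ in spec.po2_mixture])
        comp = rng.choice(len(weights), size=n_mito, p=weights)
        means = np.array([m for _, m, _ in spec.po2_mixture])[comp]
        sds = np.array([s for _, _, s in spec.po2_mixture])[comp]
        po2_vals = np.clip(rng.normal(means, sds), 0.0, None)

    calib = spec.truth_calibration()
    tau_mean_mito = np.asarray(predict_lifetime(calib, po2_vals), dtype=float)
    tau2_mito = _long_lifetime(spec, tau_mean_mito)
    a1 = spec.short_fraction

    counts = np.zeros((h, w, c), dtype=np.int32)
    tau_mean_img = np.full((h, w), np.nan)
    params_img = np.full((h, w, 4), np.nan)

    # mitochondrial photons: per-mito channel law, per-pixel Poisson totals
    basis1 = _basis(np.array([spec.short_lifetime]), edges)[0]
    for i in range(n_mito):
        sel = labels == (i + 1)
        npix = int(sel.sum())
        if npix == 0:
            continue
        basis2 = _basis(np.array([tau2_mito[i]]), edges)[0]
        weights_c = a1 * basis1 + (1.0 - a1) * basis2
        p = weights_c / weights_c.sum()
        totals = rng.poisson(spec.mito_photon_budget, size=npix)
        counts[sel] = _sample_histograms(rng, totals, p)
        tau_mean_img[sel] = tau_mean_mito[i]
        params_img[sel] = (spec.short_lifetime, tau2_mito[i], a1, 1.0 - a1)

    # uniform background (dark counts / ambient light)
    if spec.background_photon_rate > 0:
        bg = labels == 0
        totals = rng.poisson(spec.background_photon_rate, size=int(bg.sum()))
        counts[bg] = _sample_histograms(rng, totals, np.full(c, 1.0 / c))

    image = TCSPCImage(counts=counts, time_window=spec.time_window,
                       condition=spec.condition, imposed_po2=po2_override)
    truth = GroundTruth(
        mito_label_image=labels,
        per_mito_po2={i + 1: float(po2_vals[i]) for i in range(n_mito)},
        per_pixel_tau_mean=tau_mean_img,
        per_pixel_params=params_img,
    )
    return image, truth


def generate_calibration_series(spec: SceneSpec,
                                imposed_po2_levels: Sequence[float]
                                ) -> list[tuple[float, TCSPCImage, GroundTruth]]:
    """One image per imposed pO2 level, every mitochondrion at that level.

    Emulates the rotenone reference condition: with respiration blocked the
    intracellular pO2 equals the media-imposed pO2, so these images anchor
    the calibration curve.  Each level gets an independent child seed of
    ``spec.seed``.
    """
    levels = list(imposed_po2_levels)
    if not levels:
        raise ValueError("need at least one imposed pO2 level")
    if any(l < 0 for l in levels):
        raise ValueError("imposed pO2 levels must be >= 0")
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(levels)) % (2 ** 31)
    out = []
    for level, child_seed in zip(levels, seeds):
        level_spec = replace(spec, seed=int(child_seed),
                             condition=f"rotenone@{level:g}mmHg")
        image, truth = generate_decay_image(level_spec, po2_override=float(level))
        out.append((float(level), image, truth))
    return out


def generate_ct_table(spec: CtSpec) -> pd.DataFrame:
    """Synthetic qPCR plate as a tidy table.

    Columns: sample, target, role, dilution, ct_1..ct_n.  One row per
    (sample, target, role) in ``spec.true_abundance``, deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (sample, target, role), abundance in spec.true_abundance.items():
        if abundance <= 0:
            raise ValueError(f"non-positive abundance for {(sample, target, role)}")
        dilution = float(spec.dilution.get(role, 1.0))
        ct_true = spec.intercept - math.log(abundance / dilution, spec.efficiency)
        cts = ct_true + rng.normal(0.0, spec.replicate_sd, size=spec.n_replicates)
        row = {"sample": sample, "target": target, "role": role, "dilution": dilution}
        row.update({f"ct_{i + 1}": float(v) for i, v in enumerate(cts)})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_reads(genome_length: int, n_reads: int, read_length: int,
                   peaks: Sequence[tuple[float, float, float]] = (),
                   seed: int = 0) -> pd.DataFrame:
    """Read intervals on a circular genome with optional enriched peaks.

    Start positions are drawn from a density proportional to
    ``1 + sum_j (fold_j - 1) * exp(-d_j^2 / (2 width_j^2))`` where ``d_j`` is
    the circular distance to peak center ``j``; at a peak center the local
    read density is ``fold`` times background.  Intervals are 0-based
    half-open in unwrapped coordinates (``end`` may exceed ``genome_length``
    when a read wraps the origin).
    """
    if not (genome_length > read_length > 0):
        raise ValueError("need genome_length > read_length > 0")
    for _, _, fold in peaks:
        if fold < 1:
            raise ValueError("peak fold enrichment must be >= 1")
    rng = np.random.default_rng(seed)

    # mixture sampling: background mass = L, each peak adds (fold-1)*width*sqrt(2*pi)
    peak_mass = np.array([(fold - 1.0) * width * math.sqrt(2.0 * math.pi)
                          for _, width, fold in peaks])
    masses = np.concatenate([[float(genome_length)], peak_mass])
    probs = masses / masses.sum()
    comp = rng.choice(len(masses), size=n_reads, p=probs)

    starts = np.empty(n_reads, dtype=np.int64)
    bg = comp == 0
    starts[bg] = rng.integers(0, genome_length, size=int(bg.sum()))
    for j, (center, width, _fold) in enumerate(peaks, start=1):
        sel = comp == j
        pos = rng.normal(center, width, size=int(sel.sum()))
        starts[sel] = np.floor(pos).astype(np.int64) % genome_length
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    return pd.DataFrame({
        "start": starts,
        "end": starts + read_length,
        "strand": strands,
    })
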