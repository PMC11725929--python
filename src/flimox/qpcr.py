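"""qPCR enrichment arithmetic and binned/smoothed coverage signal.

Covers the quantification steps downstream of a DNA:RNA-hybrid
immunoprecipitation (DRIP) experiment on the circular mitochondrial genome:

* 2^dCt relative quantification of IP versus input with sample-dilution
  correction (IP diluted 10-fold, input 100-fold is the typical layout),
  optionally normalized against an RNase H-treated IP (the hybrid-specific
  negative control);
* mitochondrial DNA copy number as the nd4 (mitochondrial) to mTert
  (nuclear) abundance ratio, efficiency^(Ct_mTert - Ct_nd4);
* fixed-width binned RPKM coverage of read intervals on a circular contig,
  with sliding-window (boxcar) smoothing and per-bin normalization against
  an input or RNase H reference track.

The dilution-correction convention: the undiluted template amount is
proportional to ``dilution * efficiency^(-Ct)`` — a more dilute aliquot of
the same source crosses threshold later, so multiplying back by the fold
dilution recovers comparable quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "CtRecord",
    "MeanCt",
    "EnrichmentResult",
    "BinnedSignal",
    "mean_ct",
    "drip_enrichment",
    "rnaseh_normalize",
    "mtdna_copy_number",
    "binned_rpkm",
    "smooth_signal",
    "normalize_tracks",
    "write_bedgraph",
]

ROLES = ("IP", "input", "RNaseH-IP")

#: Replicates deviating more than this many cycles from the record median
#: are flagged as outliers (flagged, not dropped).
REPLICATE_OUTLIER_CYCLES = 1.0


@dataclass
class CtRecord:
    """One qPCR measurement: a (sample, target, role) with replicate Cts.

    ``dilution`` is the fold dilution applied before the plate;
    ``input_fraction`` is the share of sonicated material kept as input
    (2% in the standard protocol), used only when explicitly correcting.
    """

    sample: str
    target: str
    role: str
    dilution: float
    ct_replicates: Sequence[float]
    input_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1 fold")
        if len(self.ct_replicates) < 1:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValueError("Ct values must be positive")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass
class MeanCt:
    """Replicate mean with per-replicate outlier flags."""

    value: float
    outlier_flags: list[bool]

    @property
    def any_outlier(self) -> bool:
        return any(self.outlier_flags)

    def __float__(self) -> float:
        return self.value


@dataclass
class EnrichmentResult:
    """Dilution-corrected IP/input enrichment for one sample x target."""

    sample: str
    target: str
    ip_over_input: float
    rnaseh_normalized: Optional[float] = None
    dilution_corrected: bool = True
    input_fraction_corrected: bool = False


@dataclass
class BinnedSignal:
    """Per-bin RPKM over a circular genome."""

    genome_length: int
    bin_size: int
    values: np.ndarray
    total_reads: int
    smoothed: bool = False
    norm_mode: Optional[str] = None

    def __post_init__(self) -> None:
        expected = math.ceil(self.genome_length / self.bin_size)
        if len(self.values) != expected:
            raise ValueError(f"expected {expected} bins, got {len(self.values)}")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size


def mean_ct(record: CtRecord) -> MeanCt:
    """Arithmetic mean of the Ct replicates, flagging stray replicates.

    A replicate more than one cycle from the record median is flagged (a
    two-fold discrepancy in apparent template), but still contributes to
    the mean — dropping is left to the caller.
    """
    cts = np.asarray(record.ct_replicates, dtype=float)
    median = float(np.median(cts))
    flags = [bool(abs(ct - median) > REPLICATE_OUTLIER_CYCLES) for ct in cts]
    return MeanCt(value=float(cts.mean()), outlier_flags=flags)


def _undiluted_quantity(record: CtRecord, efficiency: float = 2.0) -> float:
    return record.dilution * efficiency ** (-mean_ct(record).value)


def drip_enrichment(ip: CtRecord, input_record: CtRecord,
                    correct_input_fraction: bool = False,
                    efficiency: float = 2.0) -> EnrichmentResult:
    """IP/input enrichment by 2^dCt with sample-dilution correction.

    ``ip_over_input = (dil_IP * E^-Ct_IP) / (dil_input * E^-Ct_input)``;
    with ``correct_input_fraction`` the input quantity is additionally
    scaled up by 1/input_fraction to represent the whole lysate.
    """
    if ip.target != input_record.target:
        raise ValueError("IP and input records must share a target")
    if ip.role not in ("IP", "RNaseH-IP") or input_record.role != "input":
        raise ValueError("expected an IP-role record and an input-role record")
    numerator = _undiluted_quantity(ip, efficiency)
    denominator = _undiluted_quantity(input_record, efficiency)
    if correct_input_fraction:
        denominator /= input_record.input_fraction
    return EnrichmentResult(
        sample=ip.sample, target=ip.target,
        ip_over_input=numerator / denominator,
        input_fraction_corrected=correct_input_fraction,
    )


def rnaseh_normalize(enr: EnrichmentResult,
                     enr_rnaseh: EnrichmentResult) -> EnrichmentResult:
    """Normalize an enrichment against its RNase H-treated control."""
    if enr.target != enr_rnaseh.target:
        raise ValueError("enrichments must share a target")
    if enr_rnaseh.ip_over_input <= 0:
        raise ValueError("RNase H control enrichment must be positive")
    return replace(enr, rnaseh_normalized=enr.ip_over_input / enr_rnaseh.ip_over_input)


def mtdna_copy_number(ct_nd4: CtRecord, ct_mtert: CtRecord,
                      efficiency: float = 2.0) -> float:
    """mtDNA copy number as the nd4/mTert ratio: efficiency^(Ct_mTert - Ct_nd4).

    nd4 is mitochondrially encoded, mTert is the nuclear single-copy
    internal control; both are assumed measured on the same template.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    delta = mean_ct(ct_mtert).value - mean_ct(ct_nd4).value
    return float(efficiency ** delta)


def binned_rpkm(reads: pd.DataFrame, genome_length: int,
                bin_size: int = 20) -> BinnedSignal:
    """Fixed-width binned RPKM of read intervals on a circular genome.

    Each read contributes to the single bin containing its 5'-most
    coordinate (interval start on the plus strand, last covered base on the
    minus strand), with circular wrap-around.  RPKM = count /
    (bin_size/1000 kb * total/1e6 M reads).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1 bp")
    total = len(reads)
    if total == 0:
        raise ValueError("read table is empty")
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    strand = reads["strand"].to_numpy()
    five_prime = np.where(strand == "-", (end - 1) % genome_length,
                          start % genome_length)
    n_bins = math.ceil(genome_length / bin_size)
    counts = np.bincount(five_prime // bin_size, minlength=n_bins).astype(float)
    rpkm = counts / ((bin_size / 1000.0) * (total / 1e6))
    return BinnedSignal(genome_length=genome_length, bin_size=bin_size,
                        values=rpkm, total_reads=total)


def smooth_signal(signal: BinnedSignal, smooth_length: int = 45) -> BinnedSignal:
    """Circular boxcar smoothing over a window of ``smooth_length`` bp.

    The window spans ceil(smooth_length / bin_size) bins, rounded up to odd
    so it centers on each bin; the circular mean of the track is preserved
    exactly.
    """
    if smooth_length < signal.bin_size:
        raise ValueError("smooth_length must be >= bin_size")
    n_window = math.ceil(smooth_length / signal.bin_size)
    if n_window % 2 == 0:
        n_window += 1
    if n_window > signal.n_bins:
        raise ValueError("smoothing window exceeds the genome")
    smoothed = uniform_filter1d(signal.values.astype(float), size=n_window,
                                mode="wrap")
    return replace(signal, values=smoothed, smoothed=True)


def normalize_tracks(ip: BinnedSignal, reference: BinnedSignal,
                     mode: str = "input",
                     pseudocount: float = 0.1) -> BinnedSignal:
    """Per-bin ratio of an IP track to an input or RNase H reference track.

    A pseudocount (RPKM units) added to the reference keeps empty reference
    bins from exploding the ratio.
    """
    if mode not in ("input", "rnaseh"):
        raise ValueError("mode must be 'input' or 'rnaseh'")
    if (ip.genome_length, ip.bin_size) != (reference.genome_length, reference.bin_size):
        raise ValueError("tracks must share genome length and bin size")
    ratio = ip.values / (reference.values + pseudocount)
    return replace(ip, values=ratio, norm_mode=mode)


def write_bedgraph(signal: BinnedSignal, path, chrom: str = "chrM") -> None:
    """Write a track as bedGraph (0-based, half-open) on one circular contig."""
    starts = signal.bin_starts()
    ends = np.minimum(starts + signal.bin_size, signal.genome_length)
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, signal.values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
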