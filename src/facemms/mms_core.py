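"""Glued speed series, peak extraction, and micro-movement spikes.

Within each face region the per-landmark speed segments are concatenated
("glued") in a fixed ascending landmark order.  The amplitudes of the
speed peaks are fitted with a Gamma distribution to obtain the empirical
Gamma mean; absolute deviations of the glued series from that mean are
then peak-extracted and each deviation peak P is standardized by its
flanking local minima into a micro-movement spike

    spike = P / (P + (m_left + m_right) / 2)   in (0, 1].

The spike value is unitless and invariant to overall speed scale, which
dampens anatomical size differences across faces.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from facemms import errors
from facemms.preprocessing import RegionPartition, SpeedSeries

MIN_PEAKS_FOR_FIT = 30
MAX_NONPOSITIVE_FRACTION = 0.05


@dataclasses.dataclass
class GluedSpeedSeries:
    region: str
    landmarks: tuple[int, ...]  # glue order, recorded for reproducibility
    values: np.ndarray  # length = len(landmarks) * F

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class PeakSet:
    indices: np.ndarray
    amplitudes: np.ndarray

    def __len__(self) -> int:
        return self.indices.shape[0]


@dataclasses.dataclass
class MMSSeries:
    """Micro-movement spikes: standardized deviation peaks in (0, 1].

    spike_values holds the spikes in peak order; full_series has the same
    length as the parent deviation series with zeros off the peaks.
    """

    spike_positions: np.ndarray
    spike_values: np.ndarray
    full_series: np.ndarray


def glue_region(
    speed: SpeedSeries,
    region: str,
    partition: RegionPartition,
    order: tuple[int, ...] | None = None,
) -> GluedSpeedSeries:
    """Concatenate the region's per-landmark speed segments.

    Default glue order is ascending landmark index; ``order`` overrides it
    (must be a permutation of the region's landmarks).
    """
    landmarks = partition[region]
    if order is None:
        order = tuple(sorted(landmarks))
    elif set(order) != set(landmarks):
        raise errors.IncompleteRegionError(
            f"glue order is not a permutation of region {region}"
        )
    segments = []
    for lm in order:
        seg = speed.values[lm]
        if not np.isfinite(seg).all():
            raise errors.IncompleteRegionError(
                f"landmark {lm} speed series not finite"
            )
        segments.append(seg)
    return GluedSpeedSeries(
        region=region, landmarks=tuple(order), values=np.concatenate(segments)
    )


def _run_compress(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse equal-value runs; return (start index, value) per run."""
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    return starts, values[starts]


def extract_peaks(values: np.ndarray) -> PeakSet:
    """All strict interior local maxima of a sample sequence.

    A plateau (run of equal values) flanked by strictly lower values on
    both sides yields one peak at the first plateau index.  Endpoints are
    never peaks.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise errors.InsufficientDataError(
            f"need >= 3 samples to find peaks, got {values.shape[0]}"
        )
    starts, runs = _run_compress(values)
    if runs.shape[0] < 3:
        return PeakSet(indices=np.array([], dtype=int), amplitudes=np.array([]))
    interior = np.arange(1, runs.shape[0] - 1)
    is_peak = (runs[interior] > runs[interior - 1]) & (
        runs[interior] > runs[interior + 1]
    )
    idx = starts[interior[is_peak]]
    return PeakSet(indices=idx, amplitudes=values[idx])


def local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of local minima, mirroring extract_peaks' plateau rule.

    A boundary sample counts as a minimum when it is <= its single
    neighbour, so descents running flat into an endpoint still provide a
    flanking minimum for standardization.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        return np.array([], dtype=int)
    starts, runs = _run_compress(values)
    out = []
    for k, s in enumerate(starts):
        left_ok = k == 0 or runs[k - 1] > runs[k]
        right_ok = k == runs.shape[0] - 1 or runs[k + 1] > runs[k]
        if left_ok and right_ok and not (k == 0 and k == runs.shape[0] - 1):
            out.append(s)
    return np.asarray(out, dtype=int)


def empirical_gamma_mean(peaks: PeakSet | np.ndarray) -> float:
    """Gamma mean a*b fitted by MLE to the speed-peak amplitudes."""
    from facemms.stochastic_signatures import fit_gamma_mle

    amplitudes = peaks.amplitudes if isinstance(peaks, PeakSet) else np.asarray(peaks)
    nonpos = amplitudes <= 0
    if amplitudes.shape[0] and nonpos.mean() > MAX_NONPOSITIVE_FRACTION:
        raise errors.DataQualityError(
            f"{nonpos.mean():.1%} of peak amplitudes are non-positive"
        )
    amplitudes = amplitudes[~nonpos]
    if amplitudes.shape[0] < MIN_PEAKS_FOR_FIT:
        raise errors.InsufficientDataError(
            f"need >= {MIN_PEAKS_FOR_FIT} positive peaks, got {amplitudes.shape[0]}"
        )
    sig = fit_gamma_mle(amplitudes)
    return sig.mean


def deviation_series(glued: GluedSpeedSeries, gamma_mean: float) -> np.ndarray:
    """Absolute deviation of every glued sample from the empirical Gamma mean."""
    if gamma_mean <= 0:
        raise errors.DomainError("gamma mean must be positive")
    return np.abs(glued.values - gamma_mean)


def mms_standardize(dev: np.ndarray) -> MMSSeries:
    """Standardize deviation peaks into micro-movement spikes.

    Each strict local maximum P is scaled by the mean of its nearest
    flanking local minima: spike = P / (P + (m_left + m_right)/2).  A peak
    with a single flanking minimum (series boundary) uses that one.
    """
    dev = np.asarray(dev, dtype=float)
    peaks = extract_peaks(dev)
    minima = local_minima(dev)
    spikes = np.empty(len(peaks))
    for j, (i, p) in enumerate(zip(peaks.indices, peaks.amplitudes)):
        left = minima[minima < i]
        right = minima[minima > i]
        flank = []
        if left.size:
            flank.append(dev[left[-1]])
        if right.size:
            flank.append(dev[right[0]])
        if not flank:
            raise errors.DomainError(f"peak at {i} has no flanking minimum")
        m = float(np.mean(flank))
        denom = p + m
        if denom == 0:
            raise errors.DomainError(f"undefined spike at {i}: peak + minima = 0")
        spikes[j] = p / denom
    full = np.zeros_like(dev)
    full[peaks.indices] = spikes
    return MMSSeries(
        spike_positions=peaks.indices, spike_values=spikes, full_series=full
    )
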