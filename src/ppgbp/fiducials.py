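"""PPG fiducial detection: pulse peaks, troughs, IBI series, pulse quality.

Peak detection adapts the Pan-Tompkins QRS detector to the PPG pulse band:
band-pass (0.5-8 Hz) -> derivative -> squaring -> moving-window integration
(150 ms) -> adaptive dual-threshold picking with a 250 ms refractory period
and search-back -> crest refinement (argmax of a lightly smoothed signal in
a forward-biased -100/+300 ms window, then a cubic local-max fit over the
crest; the integrated-energy burst leads the systolic peak by roughly half
the upstroke time). All thresholds are data-adaptive, so detection is
invariant to positive amplitude scaling.

Troughs are defined as the inter-peak minima, which guarantees strict
peak/trough interleaving. IBIs from peaks feed systolic estimation, IBIs
from troughs feed diastolic estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, NoBeatsError, SamplingError
from .signal_io import SampledSignal


@dataclass(frozen=True)
class FiducialConfig:
    """Constants of the PPG-adapted Pan-Tompkins pipeline."""

    band_hz: tuple[float, float] = (0.5, 8.0)
    filter_order: int = 2
    integration_window_s: float = 0.150
    refractory_s: float = 0.250
    # the integrated-energy peak sits mid-upstroke, ~half the systolic
    # upstroke time ahead of the raw peak, so refinement looks further
    # forward than back
    refine_back_s: float = 0.100
    refine_forward_s: float = 0.300
    refine_smooth_s: float = 0.040  # light smoothing before argmax refinement
    refine_vertex_s: float = 0.096  # half-window of the cubic crest fit
    searchback_factor: float = 1.66   # missed-beat search-back at 1.66x mean RR
    threshold_fraction: float = 0.25  # T1 = NPK + frac*(SPK-NPK)
    leading_trough_window_s: float = 1.5


@dataclass(frozen=True)
class FiducialSet:
    """Detected peak and trough sample indices on one signal."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peak_indices, dtype=int)
        troughs = np.asarray(self.trough_indices, dtype=int)
        object.__setattr__(self, "peak_indices", peaks)
        object.__setattr__(self, "trough_indices", troughs)
        for name, idx in (("peaks", peaks), ("troughs", troughs)):
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def is_interleaved(self) -> bool:
        """True when exactly one trough lies between each consecutive peak
        pair (holds by construction after reconciliation; artifact sets may
        violate it and are handled by segmentation's skip rule)."""
        peaks, troughs = self.peak_indices, self.trough_indices
        return all(
            np.sum((troughs > a) & (troughs < b)) == 1
            for a, b in zip(peaks[:-1], peaks[1:])
        )


@dataclass(frozen=True)
class IBISeries:
    """Interbeat intervals (s) anchored on peaks or troughs."""

    intervals: np.ndarray
    source: str                      # "peaks" | "troughs"
    times: np.ndarray                # interval end times, s
    n_dropped: int = 0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.source not in ("peaks", "troughs"):
            raise ValueError(f"source must be 'peaks' or 'troughs', got {self.source!r}")
        if iv.size and not (np.all(iv > 0) and np.all(iv < 5.0)):
            raise ValueError("intervals must lie in (0, 5) s")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class PulseSegment:
    """One trough-to-trough pulse with the systolic peak inside it."""

    samples: np.ndarray
    fs: float
    peak_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not 0 < self.peak_offset < self.samples.size - 1:
            raise ValueError("peak_offset must be interior to the segment")

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.fs


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _integrated_signal(x: np.ndarray, fs: float, cfg: FiducialConfig) -> np.ndarray:
    nyq = fs / 2.0
    lo, hi = cfg.band_hz
    hi = min(hi, 0.95 * nyq)
    sos = sps.butter(cfg.filter_order, [lo / nyq, hi / nyq], btype="band", output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filtered) * fs
    squared = deriv ** 2
    w = max(1, int(round(cfg.integration_window_s * fs)))
    return np.convolve(squared, np.ones(w) / w, mode="same")


def detect_pulse_peaks(
    sig: SampledSignal, cfg: FiducialConfig | None = None
) -> np.ndarray:
    """Systolic peak sample indices via the PPG-adapted Pan-Tompkins pipeline."""
    cfg = cfg or FiducialConfig()
    if sig.fs < 50:
        raise SamplingError(f"fs must be >= 50 Hz for peak detection, got {sig.fs}")
    if sig.duration_s < 10:
        raise SamplingError("need at least 10 s of signal for peak detection")
    x = sig.samples
    if np.ptp(x) == 0:
        raise NoBeatsError("signal is constant; no pulses present")

    integ = _integrated_signal(x, sig.fs, cfg)
    refractory = int(round(cfg.refractory_s * sig.fs))
    cand, _ = sps.find_peaks(integ, distance=max(1, refractory))
    if cand.size == 0:
        raise NoBeatsError("no candidate pulses found in integrated signal")

    # adaptive dual thresholds (running signal/noise peak estimates)
    spk = float(np.max(integ[: int(2 * sig.fs)])) if integ.size else 0.0
    npk = float(np.mean(integ[: int(2 * sig.fs)]))
    accepted: list[int] = []
    rr_history: list[float] = []
    noise_cands: list[int] = []
    for c in cand:
        t1 = npk + cfg.threshold_fraction * (spk - npk)
        if integ[c] >= t1:
            if accepted and rr_history:
                gap = (c - accepted[-1]) / sig.fs
                mean_rr = float(np.mean(rr_history[-8:]))
                if gap > cfg.searchback_factor * mean_rr:
                    # search-back among rejected candidates at half threshold
                    t2 = 0.5 * t1
                    missed = [m for m in noise_cands
                              if accepted[-1] + refractory < m < c - refractory
                              and integ[m] >= t2]
                    if missed:
                        best = max(missed, key=lambda m: integ[m])
                        rr_history.append((best - accepted[-1]) / sig.fs)
                        accepted.append(best)
            if accepted:
                rr_history.append((c - accepted[-1]) / sig.fs)
            accepted.append(c)
            spk = 0.125 * float(integ[c]) + 0.875 * spk
        else:
            noise_cands.append(c)
            npk = 0.125 * float(integ[c]) + 0.875 * npk

    if not accepted:
        raise NoBeatsError("no pulses passed the adaptive threshold")

    # refine to the signal maximum in an asymmetric window around the
    # integrated-energy candidate; a short moving average suppresses
    # sample-level noise on the flat pulse crest
    back = int(round(cfg.refine_back_s * sig.fs))
    fwd = int(round(cfg.refine_forward_s * sig.fs))
    w = max(1, int(round(cfg.refine_smooth_s * sig.fs)) | 1)  # odd width
    xs = np.convolve(x, np.ones(w) / w, mode="same") if w > 1 else x
    vh = int(round(cfg.refine_vertex_s * sig.fs))
    refined = []
    for c in accepted:
        lo = max(0, c - back)
        hi = min(x.size, c + fwd + 1)
        c0 = lo + int(np.argmax(xs[lo:hi]))
        if vh >= 3:
            # cubic fit to the smoothed crest: averages out sample-level
            # noise on the flat pulse top while capturing the left/right
            # curvature asymmetry that would bias a parabola vertex
            vlo, vhi = max(0, c0 - vh), min(x.size, c0 + vh + 1)
            d = (np.arange(vlo, vhi) - c0).astype(float)
            coef = np.polyfit(d, xs[vlo:vhi], 3)
            der = np.polyder(coef)
            roots = np.roots(der)
            roots = roots[np.isreal(roots)].real
            maxima = [r for r in roots
                      if np.polyval(np.polyder(der), r) < 0 and abs(r) <= vh]
            if maxima:
                r = min(maxima, key=abs)
                c0 = int(round(np.clip(c0 + r, vlo, vhi - 1)))
        refined.append(c0)
    refined = np.unique(refined)

    # enforce refractory on refined indices, keeping the taller peak
    keep: list[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < refractory:
            if xs[idx] > xs[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int)


def detect_pulse_troughs(sig: SampledSignal, peaks: np.ndarray) -> np.ndarray:
    """One trough per inter-peak gap (signal argmin), plus a leading trough
    before the first peak when a local minimum exists there."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise InsufficientDataError("need >= 2 peaks to locate troughs")
    x = sig.samples
    troughs = []
    cfg_window = int(round(FiducialConfig().leading_trough_window_s * sig.fs))
    lead_lo = max(0, peaks[0] - cfg_window)
    if peaks[0] - lead_lo >= 2:
        seg = x[lead_lo: peaks[0]]
        m = lead_lo + int(np.argmin(seg))
        # accept if interior local minimum, or the record-leading onset sample
        if (0 < m < peaks[0] and
                (m == 0 or x[m] <= x[m - 1]) and x[m] <= x[m + 1]):
            troughs.append(m)
        elif m == 0 and x[0] <= x[1]:
            troughs.append(m)
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(a + 1 + int(np.argmin(x[a + 1: b])))
    return np.asarray(troughs, dtype=int)


def detect_fiducials(
    sig: SampledSignal, cfg: FiducialConfig | None = None
) -> FiducialSet:
    """Peaks + interleaved troughs in one call."""
    peaks = detect_pulse_peaks(sig, cfg)
    troughs = detect_pulse_troughs(sig, peaks)
    return FiducialSet(peak_indices=peaks, trough_indices=troughs, fs=sig.fs)


# ---------------------------------------------------------------------------
# IBI series and pulse segmentation
# ---------------------------------------------------------------------------

#: physiologic interbeat-interval bounds, s
PHYSIOLOGIC_IBI_BOUNDS = (0.3, 2.0)


def build_ibi_series(
    anchors: np.ndarray,
    fs: float,
    source: str,
    physiologic_filter: bool = True,
    bounds: tuple[float, float] = PHYSIOLOGIC_IBI_BOUNDS,
) -> IBISeries:
    """Successive anchor differences in seconds, optionally screened to
    physiologic bounds (dropped count retained on the result)."""
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size < 3:
        raise InsufficientDataError(f"need >= 3 anchors, got {anchors.size}")
    intervals = np.diff(anchors) / fs
    times = anchors[1:] / fs
    n_dropped = 0
    if physiologic_filter:
        ok = (intervals >= bounds[0]) & (intervals <= bounds[1])
        n_dropped = int(np.sum(~ok))
        intervals, times = intervals[ok], times[ok]
    return IBISeries(intervals=intervals, source=source, times=times,
                     n_dropped=n_dropped)


def segment_pulses(
    sig: SampledSignal, fid: FiducialSet
) -> tuple[list[PulseSegment], int]:
    """Trough-to-trough segments containing exactly one detected peak.

    Spans with zero or multiple peaks are skipped; the skip count is
    returned alongside the segments.
    """
    x = sig.samples
    troughs = fid.trough_indices
    peaks = fid.peak_indices
    segments: list[PulseSegment] = []
    skipped = 0
    for a, b in zip(troughs[:-1], troughs[1:]):
        inside = peaks[(peaks > a) & (peaks < b)]
        if inside.size != 1:
            skipped += 1
            continue
        segments.append(PulseSegment(samples=x[a: b + 1], fs=sig.fs,
                                     peak_offset=int(inside[0] - a)))
    return segments, skipped


def pulse_quality_autocorrelation(
    segments: list[PulseSegment],
    threshold: float = 0.9,
    resample_n: int = 100,
) -> np.ndarray:
    """Quality mask: True where a pulse's mean correlation with its adjacent
    pulses (after linear time-normalisation to a common length) reaches the
    threshold.

    Pulses with undefined correlation (constant after normalisation) fail.
    """
    if len(segments) < 2:
        raise InsufficientDataError("need >= 2 segments for quality screening")
    grid = np.linspace(0.0, 1.0, resample_n)
    normed = []
    for seg in segments:
        xp = np.linspace(0.0, 1.0, seg.samples.size)
        normed.append(np.interp(grid, xp, seg.samples))
    normed = np.asarray(normed)

    def corr(u: np.ndarray, v: np.ndarray) -> float:
        su, sv = np.std(u), np.std(v)
        if su == 0 or sv == 0:
            return 0.0
        return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))

    adjacent = np.array([corr(normed[i], normed[i + 1])
                         for i in range(len(segments) - 1)])
    mean_corr = np.empty(len(segments))
    mean_corr[0] = adjacent[0]
    mean_corr[-1] = adjacent[-1]
    for i in range(1, len(segments) - 1):
        mean_corr[i] = 0.5 * (adjacent[i - 1] + adjacent[i])
    return mean_corr >= threshold
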