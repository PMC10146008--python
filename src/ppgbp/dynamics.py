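"""Pulse-rate-variability features of an interbeat-interval series.

Fifteen features spanning the standard HRV families:

* time domain -- mean IBI, SDNN, RMSSD, NNx, pNNx (x = 50 ms default,
  strict inequality);
* geometric -- triangular index (PRVTi) and TINN from a 1/128 s histogram;
* frequency domain -- LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) band powers of
  the cubic-interpolated 4 Hz tachogram (Welch periodogram), and LF/HF;
* Poincare -- SD1/SD2 of the lag-1 return plot;
* nonlinear -- sample entropy SampEn(m=2, r=0.2*SD) and the DFA scaling
  exponents alpha1 (boxes 4-16) and alpha2 (boxes 16-64).

Population (n-denominator) variance is used throughout, which makes the
Poincare identities exact: sd1^2 = Var(successive differences)/2.

Undefined features (constant series, too-short records) are carried as NaN
with a reason string, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .errors import InsufficientDataError
from .fiducials import IBISeries

DYNAMICS_NAMES = [
    "mean_ibi", "sdnn", "rmssd", "nnx", "pnnx", "prvti", "tinn",
    "lf", "hf", "lf_hf", "sd1", "sd2", "sampen", "alpha1", "alpha2",
]

#: dynamics subset feeding the composite estimator's final stage
DYN7_NAMES = ["sdnn", "prvti", "tinn", "lf", "hf", "alpha1", "alpha2"]


@dataclass(frozen=True)
class DynamicsConfig:
    x_ms: float = 50.0
    resample_hz: float = 4.0
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    bin_width_s: float = 1.0 / 128.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    dfa1_boxes: tuple[int, int] = (4, 16)
    dfa2_boxes: tuple[int, int] = (16, 64)
    welch_segment_s: float = 120.0

    def __post_init__(self) -> None:
        if not (self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1]):
            raise ValueError("LF and HF bands must be disjoint and ordered")
        if not (self.dfa1_boxes[0] < self.dfa1_boxes[1] <= self.dfa2_boxes[0]
                < self.dfa2_boxes[1]):
            raise ValueError("DFA box ranges must be increasing and non-overlapping")


@dataclass(frozen=True)
class DynamicsFeatureVector:
    """All 15 features; undefined entries are NaN with a reason recorded."""

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or DYNAMICS_NAMES
        return np.asarray([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain(
    ibi: IBISeries, cfg: DynamicsConfig | None = None, min_n: int = 10
) -> tuple[float, float, float, int, float]:
    """mean IBI, SDNN, RMSSD (s), NNx count and pNNx (%)."""
    cfg = cfg or DynamicsConfig()
    x = ibi.intervals
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} intervals, got {x.size}")
    diffs = np.diff(x)
    mean_ibi = float(np.mean(x))
    sdnn = float(np.std(x))                       # population SD
    rmssd = float(np.sqrt(np.mean(diffs ** 2))) if diffs.size else 0.0
    nnx = int(np.sum(np.abs(diffs) > cfg.x_ms / 1000.0))
    pnnx = 100.0 * nnx / diffs.size if diffs.size else 0.0
    return mean_ibi, sdnn, rmssd, nnx, pnnx


# ---------------------------------------------------------------------------
# geometric
# ---------------------------------------------------------------------------

def _histogram(x: np.ndarray, bw: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.floor(np.min(x) / bw) * bw
    hi = np.ceil(np.max(x) / bw + 1e-12) * bw
    nbins = max(1, int(round((hi - lo) / bw)))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bw))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def geometric(
    ibi: IBISeries, cfg: DynamicsConfig | None = None, min_n: int = 20
) -> tuple[float, float]:
    """Triangular index (total count / mode-bin count) and TINN (s).

    TINN is the base width M - N of the least-squares triangle fitted to the
    interval histogram with its apex fixed at the mode bin.
    """
    cfg = cfg or DynamicsConfig()
    x = ibi.intervals
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} intervals, got {x.size}")
    counts, centers = _histogram(x, cfg.bin_width_s)
    m = int(np.argmax(counts))
    prvti = float(x.size / counts[m])
    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        return prvti, 0.0

    def tri(ni: int, mj: int) -> np.ndarray:
        q = np.zeros_like(counts)
        if mj > m:
            right = np.arange(m, mj + 1)
            q[right] = counts[m] * (centers[mj] - centers[right]) / (
                centers[mj] - centers[m])
        if ni < m:
            left = np.arange(ni, m + 1)
            q[left] = counts[m] * (centers[left] - centers[ni]) / (
                centers[m] - centers[ni])
        q[m] = counts[m]
        return q

    best = (np.inf, 0.0)
    for ni in range(0, m + 1):
        for mj in range(m, counts.size):
            err = float(np.sum((counts - tri(ni, mj)) ** 2))
            if err < best[0]:
                best = (err, float(centers[mj] - centers[ni]))
    return prvti, best[1]


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def spectral(
    ibi: IBISeries, cfg: DynamicsConfig | None = None
) -> tuple[float, float, float]:
    """LF/HF band powers (s^2) of the uniformly resampled tachogram.

    The tachogram is cubic-interpolated to ``resample_hz``, mean-removed,
    and analysed with a Welch averaged periodogram (120 s segments, 50%
    overlap). ``lf_hf`` is NaN when HF is zero.
    """
    cfg = cfg or DynamicsConfig()
    t, x = ibi.times, ibi.intervals
    if t.size < 4 or (t[-1] - t[0]) < 60.0:
        raise InsufficientDataError("need >= 60 s of intervals for spectral features")
    grid = np.arange(t[0], t[-1], 1.0 / cfg.resample_hz)
    tach = CubicSpline(t, x)(grid)
    tach = tach - np.mean(tach)
    nperseg = min(tach.size, int(cfg.welch_segment_s * cfg.resample_hz))
    freqs, psd = welch(tach, fs=cfg.resample_hz, nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")

    def band_power(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(cfg.lf_band)
    hf = band_power(cfg.hf_band)
    lf_hf = lf / hf if hf > 0 else float("nan")
    return lf, hf, lf_hf


# ---------------------------------------------------------------------------
# Poincare
# ---------------------------------------------------------------------------

def poincare(ibi: IBISeries, min_n: int = 10) -> tuple[float, float]:
    """SD1 and SD2 of the lag-1 return plot (population SD conventions)."""
    x = ibi.intervals
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} intervals, got {x.size}")
    d = (x[1:] - x[:-1]) / np.sqrt(2.0)
    s = (x[1:] + x[:-1]) / np.sqrt(2.0)
    return float(np.std(d)), float(np.std(s))


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def sample_entropy(
    ibi: IBISeries | np.ndarray,
    cfg: DynamicsConfig | None = None,
    min_n: int = 50,
) -> float:
    """SampEn(m, r) = -ln(A/B) with Chebyshev distance, self-matches
    excluded, and r = ``sampen_r_factor`` x population SD.

    NaN (undefined) for constant series (r = 0) or when no template pair
    matches at length m+1.
    """
    cfg = cfg or DynamicsConfig()
    x = np.asarray(ibi.intervals if isinstance(ibi, IBISeries) else ibi, dtype=float)
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} intervals, got {x.size}")
    m = cfg.sampen_m
    sd = float(np.std(x))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        return float("nan")  # constant series: r degenerates to 0
    r = cfg.sampen_r_factor * sd
    n = x.size
    nt = n - m  # template count for both lengths
    Xm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    Xm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]

    def pair_count(templates: np.ndarray) -> int:
        dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1)
        iu = np.triu_indices(templates.shape[0], k=1)
        return int(np.sum(dist[iu] <= r))

    B = pair_count(Xm)
    A = pair_count(Xm1)
    if B == 0 or A == 0:
        return float("nan")
    return float(-np.log(A / B))


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _dfa_fluctuations(x: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    y = np.cumsum(x - np.mean(x))
    out = np.empty(box_sizes.size)
    t = np.arange(y.size, dtype=float)
    for i, n in enumerate(box_sizes):
        nbox = y.size // n
        res2 = 0.0
        for b in range(nbox):
            seg = y[b * n:(b + 1) * n]
            ts = t[b * n:(b + 1) * n]
            coef = np.polyfit(ts, seg, 1)
            res2 += float(np.sum((seg - np.polyval(coef, ts)) ** 2))
        # finite-size deflation of linear detrending: for an uncorrelated
        # series E[F^2(n)] = sigma^2 (n^2-4)/(15 n); the factor below makes
        # the white-noise expectation exactly proportional to n^(2*0.5)
        out[i] = np.sqrt(res2 / (nbox * n)) * n / np.sqrt(n * n - 4.0)
    return out


def dfa(
    ibi: IBISeries | np.ndarray,
    cfg: DynamicsConfig | None = None,
) -> tuple[float, float]:
    """DFA scaling exponents alpha1 (boxes 4-16) and alpha2 (16-64).

    alpha1 needs >= 100 intervals and alpha2 >= 300; either is NaN when its
    requirement fails or when the detrended fluctuation vanishes (e.g. a
    linear ramp, which the per-box linear detrend removes exactly).
    """
    cfg = cfg or DynamicsConfig()
    x = np.asarray(ibi.intervals if isinstance(ibi, IBISeries) else ibi, dtype=float)

    def alpha(box_range: tuple[int, int], min_len: int) -> float:
        if x.size < min_len:
            return float("nan")
        sizes = np.arange(box_range[0], box_range[1] + 1)
        sizes = sizes[sizes <= x.size // 2]
        if sizes.size < 3:
            return float("nan")
        F = _dfa_fluctuations(x, sizes)
        if np.any(F < 1e-10):
            return float("nan")
        return float(np.polyfit(np.log(sizes), np.log(F), 1)[0])

    return alpha(cfg.dfa1_boxes, 100), alpha(cfg.dfa2_boxes, 300)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_dynamics(
    ibi: IBISeries, cfg: DynamicsConfig | None = None
) -> DynamicsFeatureVector:
    """All 15 features; components whose preconditions fail are NaN with a
    reason, and downstream models reject rows with missing inputs."""
    cfg = cfg or DynamicsConfig()
    values: dict[str, float] = {name: float("nan") for name in DYNAMICS_NAMES}
    missing: dict[str, str] = {}

    def attempt(names: list[str], fn) -> None:
        try:
            result = fn()
        except InsufficientDataError as exc:
            for n in names:
                missing[n] = str(exc)
            return
        for n, v in zip(names, result):
            values[n] = float(v)
            if isinstance(v, float) and np.isnan(v):
                missing[n] = "undefined (degenerate input)"

    attempt(["mean_ibi", "sdnn", "rmssd", "nnx", "pnnx"],
            lambda: time_domain(ibi, cfg))
    attempt(["prvti", "tinn"], lambda: geometric(ibi, cfg))
    attempt(["lf", "hf", "lf_hf"], lambda: spectral(ibi, cfg))
    attempt(["sd1", "sd2"], lambda: poincare(ibi))
    attempt(["sampen"], lambda: (sample_entropy(ibi, cfg),))
    attempt(["alpha1", "alpha2"], lambda: dfa(ibi, cfg))
    # NaN from per-feature length rules inside dfa
    for name in ("alpha1", "alpha2"):
        if np.isnan(values[name]) and name not in missing:
            missing[name] = "insufficient intervals for this exponent"
    return DynamicsFeatureVector(values=values, missing=missing)
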