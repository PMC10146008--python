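"""Per-pulse morphology features and their record-level mPTP averages.

Each accepted pulse yields 21 features: the cardiac period (trough-to-trough
duration), systolic upstroke time (onset to peak), diastolic time (peak to
segment end, so cp = sut + dt), and -- at six fractions of the pulse height
(10/25/33/50/66/75%) -- the diastolic width, the systolic+diastolic width
sum, and the diastolic:systolic width ratio. Pulse height is measured from
the segment-onset amplitude to the peak; level crossings are linearly
interpolated, which removes sampling-rate dependence.

The record-level feature vector (mPTP, "mean point-to-point") is the
unweighted mean of each per-pulse feature over all accepted, quality-passing
pulses. Pulses where any level is not crossed on both sides of the peak are
excluded and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError, WidthUndefinedError
from .fiducials import PulseSegment

#: fractional height levels, percent
LEVELS = (10, 25, 33, 50, 66, 75)

FEATURE_NAMES_21 = (
    ["cp", "sut", "dt"]
    + [f"dw_{h}" for h in LEVELS]
    + [f"sw_dw_{h}" for h in LEVELS]
    + [f"ratio_{h}" for h in LEVELS]
)

#: 7-feature subset used by the deep morphology estimators, in declared order
SUBSET7_NAMES = ["cp", "dt", "dw_25", "dw_75", "sw_dw_33", "sw_dw_75", "ratio_10"]


@dataclass(frozen=True)
class MorphologySummary:
    """mPTP means over accepted pulses, with bookkeeping counts."""

    mptp: dict[str, float]
    n_pulses: int
    n_rejected: int

    @property
    def subset7(self) -> dict[str, float]:
        return {name: self.mptp[name] for name in SUBSET7_NAMES}


def fractional_width(pulse: PulseSegment, h: float) -> tuple[float, float]:
    """Systolic and diastolic widths (s) at fraction ``h`` of pulse height.

    The level is ``onset + h*height``. The systolic width runs from the last
    upward crossing before the peak to the peak; the diastolic width from the
    peak to the first downward crossing after it. Both crossings are linearly
    interpolated between bracketing samples.
    """
    if not 0.0 < h < 1.0:
        raise DomainError(f"h must be in (0, 1), got {h}")
    x = pulse.samples
    k = pulse.peak_offset
    onset = x[0]
    height = x[k] - onset
    if height <= 0:
        raise DomainError("pulse height (peak - onset amplitude) must be positive")
    level = onset + h * height

    # last upward crossing before the peak
    sw_t = None
    for j in range(k - 1, -1, -1):
        if x[j] <= level <= x[j + 1] and x[j + 1] > x[j]:
            frac = (level - x[j]) / (x[j + 1] - x[j])
            sw_t = (k - (j + frac)) / pulse.fs
            break
        if x[j] <= level and x[j + 1] >= level:
            sw_t = (k - (j + 0.5)) / pulse.fs  # flat bracketing, midpoint
            break
    if sw_t is None:
        raise WidthUndefinedError(f"level at h={h} never crossed before the peak")

    # first downward crossing after the peak
    dw_t = None
    for j in range(k, x.size - 1):
        if x[j] >= level >= x[j + 1] and x[j] > x[j + 1]:
            frac = (x[j] - level) / (x[j] - x[j + 1])
            dw_t = (j + frac - k) / pulse.fs
            break
    if dw_t is None:
        raise WidthUndefinedError(f"level at h={h} never crossed after the peak")
    return float(sw_t), float(dw_t)


def pulse_features(pulse: PulseSegment) -> dict[str, float]:
    """The 21 named morphology features of one pulse.

    Raises WidthUndefinedError if any of the six levels is not crossed on
    both sides of the peak; callers reject such pulses rather than impute.
    """
    cp = pulse.duration_s
    sut = pulse.peak_offset / pulse.fs
    dt = (pulse.samples.size - 1 - pulse.peak_offset) / pulse.fs
    feats = {"cp": cp, "sut": sut, "dt": dt}
    for hpct in LEVELS:
        sw, dw = fractional_width(pulse, hpct / 100.0)
        feats[f"dw_{hpct}"] = dw
        feats[f"sw_dw_{hpct}"] = sw + dw
        feats[f"ratio_{hpct}"] = dw / sw
    return {name: feats[name] for name in FEATURE_NAMES_21}


def mptp_average(
    pulses: list[PulseSegment],
    quality_mask: np.ndarray | None = None,
    min_pulses: int = 10,
) -> MorphologySummary:
    """Unweighted per-feature mean over accepted, quality-passing pulses."""
    if quality_mask is not None:
        if len(quality_mask) != len(pulses):
            raise ValueError("quality mask length must match pulse count")
        pulses = [p for p, ok in zip(pulses, quality_mask) if ok]
    rows = []
    n_rejected = 0
    for p in pulses:
        try:
            rows.append(pulse_features(p))
        except (WidthUndefinedError, DomainError):
            n_rejected += 1
    if len(rows) < min_pulses:
        raise InsufficientDataError(
            f"need >= {min_pulses} accepted pulses, got {len(rows)}"
        )
    arr = np.asarray([[r[name] for name in FEATURE_NAMES_21] for r in rows])
    mptp = dict(zip(FEATURE_NAMES_21, arr.mean(axis=0)))
    return MorphologySummary(mptp=mptp, n_pulses=len(rows), n_rejected=n_rejected)


def subset7(summary: MorphologySummary) -> np.ndarray:
    """The deep-model feature subset as an array in declared order:
    cp, dt, dw_25, dw_75, sw_dw_33, sw_dw_75, ratio_10."""
    return np.asarray([summary.mptp[name] for name in SUBSET7_NAMES], dtype=float)
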