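"""Waveform and feature-table I/O, and reference blood pressure extraction.

Reference SBP/DBP for a record come from one of two sources: a co-recorded
arterial pressure (ABP) waveform, where the reference is the mean of the
per-beat peaks (systolic) and troughs (diastolic) over the whole record, or
a provided beat-by-beat SBP/DBP series, averaged component-wise.

All delimited text uses comma separation, "." decimal, UTF-8, and a
mandatory header row for feature tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    InsufficientDataError,
    ParseError,
    SamplingError,
    SchemaError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .fiducials import FiducialSet

#: records shorter than this are rejected (spectral features need ~1 min)
MIN_RECORD_DURATION_S = 60.0


class SignalKind(str, Enum):
    PPG = "PPG"
    ABP = "ABP"


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled waveform (PPG in arbitrary units, ABP in mmHg)."""

    samples: np.ndarray
    fs: float
    kind: SignalKind = SignalKind.PPG

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatSeries:
    """Beat-by-beat systolic/diastolic pressures (mmHg)."""

    sbp_values: np.ndarray
    dbp_values: np.ndarray

    def __post_init__(self) -> None:
        sbp = np.asarray(self.sbp_values, dtype=float)
        dbp = np.asarray(self.dbp_values, dtype=float)
        object.__setattr__(self, "sbp_values", sbp)
        object.__setattr__(self, "dbp_values", dbp)
        if sbp.shape != dbp.shape:
            raise SchemaError("sbp and dbp beat series must have equal length")
        if np.any(sbp <= dbp):
            raise ValueError("every beat must satisfy sbp > dbp")

    def __len__(self) -> int:
        return self.sbp_values.size


@dataclass(frozen=True)
class BPReference:
    """Record-level reference blood pressure in mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sbp) and np.isfinite(self.dbp)):
            raise ValueError("reference BP must be finite")
        if not (self.sbp > self.dbp > 0):
            raise ValueError(f"need sbp > dbp > 0, got ({self.sbp}, {self.dbp})")


@dataclass
class SubjectRecord:
    """One subject: PPG waveform, a reference BP, and optional pressure data."""

    id: str
    ppg: SampledSignal
    reference: BPReference
    abp: SampledSignal | None = None
    beats: BeatSeries | None = None
    duration_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.duration_s == 0.0:
            self.duration_s = self.ppg.duration_s
        if abs(self.duration_s - self.ppg.duration_s) > 1.0 / self.ppg.fs:
            raise ValueError("duration_s inconsistent with PPG length")
        if self.duration_s < MIN_RECORD_DURATION_S:
            warnings.warn(
                f"record {self.id!r} is {self.duration_s:.1f} s, below the "
                f"{MIN_RECORD_DURATION_S:.0f} s floor; spectral features may "
                "be undefined",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# waveform I/O
# ---------------------------------------------------------------------------

def read_signal(
    path: str | Path,
    fs: float,
    kind: SignalKind | str = SignalKind.PPG,
) -> SampledSignal:
    """Read a waveform from one-column (values) or two-column (time, value) text.

    Two-column input is validated for uniform spacing within 1% of ``1/fs``.
    """
    path = Path(path)
    kind = SignalKind(kind)
    rows: list[list[float]] = []
    ncol = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"{path.name}: non-numeric value on line {lineno}")
            if ncol is None:
                ncol = len(vals)
                if ncol not in (1, 2):
                    raise ParseError(
                        f"{path.name}: expected 1 or 2 columns, got {ncol}"
                    )
            elif len(vals) != ncol:
                raise ParseError(f"{path.name}: ragged row on line {lineno}")
            rows.append(vals)
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.size == 0:
        raise ParseError(f"{path.name}: no numeric data")
    if data.shape[1] == 2:
        dt = np.diff(data[:, 0])
        if np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs):
            raise SamplingError(
                f"{path.name}: time column spacing deviates from 1/fs "
                f"by more than 1%"
            )
        samples = data[:, 1]
    else:
        samples = data[:, 0]
    return SampledSignal(samples=samples, fs=fs, kind=kind)


def write_signal(sig: SampledSignal, path: str | Path) -> None:
    """Write samples as one-column text at full double precision."""
    np.savetxt(path, sig.samples, fmt="%.12g")


# ---------------------------------------------------------------------------
# reference BP
# ---------------------------------------------------------------------------

def reference_bp_from_abp(abp: SampledSignal, fiducials: "FiducialSet") -> BPReference:
    """Reference BP as the mean ABP peak (SBP) and trough (DBP) amplitude.

    Averages every detected beat over the full record; requires at least 3
    peaks and 3 troughs.
    """
    if abp.kind is not SignalKind.ABP:
        raise ValueError("reference_bp_from_abp requires an ABP signal")
    peaks = np.asarray(fiducials.peak_indices)
    troughs = np.asarray(fiducials.trough_indices)
    if peaks.size < 3 or troughs.size < 3:
        raise InsufficientDataError(
            f"need >= 3 peaks and troughs, got {peaks.size} and {troughs.size}"
        )
    return BPReference(
        sbp=float(np.mean(abp.samples[peaks])),
        dbp=float(np.mean(abp.samples[troughs])),
    )


def reference_bp_from_beats(beats: BeatSeries) -> BPReference:
    """Reference BP as component-wise means of a beat-by-beat series."""
    if len(beats) < 3:
        raise InsufficientDataError(f"need >= 3 beats, got {len(beats)}")
    return BPReference(
        sbp=float(np.mean(beats.sbp_values)),
        dbp=float(np.mean(beats.dbp_values)),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(
    records: Sequence[Mapping[str, float]],
    path: str | Path,
    index: Sequence[str] | None = None,
) -> None:
    """Write one row per subject with a canonical header; 12 significant digits.

    All rows must share one schema (same feature names in the same order).
    """
    if not records:
        raise SchemaError("no records to write")
    schema = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != schema:
            raise SchemaError(f"record {i} schema differs from record 0")
    df = pd.DataFrame(list(records), index=index)
    df.to_csv(path, float_format="%.12g", index=index is not None,
              index_label="id" if index is not None else None)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)


def check_aligned(a: Sequence[str], b: Sequence[str]) -> None:
    """Raise AlignmentError unless the two subject-id sequences match."""
    if list(a) != list(b):
        raise AlignmentError("subject sets do not match between methods")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable sha256 over a JSON-serialisable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: Mapping, seed: int,
                   extra: Mapping | None = None) -> None:
    """Write a plain-JSON run manifest (config, its hash, seed, versions)."""
    import scipy

    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in config.items()},
        "config_hash": config_hash(config),
        "seed": int(seed),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
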