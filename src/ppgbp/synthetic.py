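"""Synthetic coupled PPG + ABP cohort generator with known ground-truth BP.

Real clinical PPG/pressure recordings cannot be bundled, so every downstream
stage is exercised on synthetic subjects whose blood pressure is known by
construction. Each subject is a quasi-periodic pulse train built from a
parameterised single-pulse template (systolic upstroke, diastolic decay,
optional dicrotic wave) whose geometry is coupled *monotonically* to the
assigned (SBP, DBP), plus an interbeat-interval series carrying LF/HF
oscillatory structure and Gaussian jitter.

Coupling table (all affine, fixed package constants):

==========================  =============================================
quantity                    coupling
==========================  =============================================
systolic upstroke fraction  u = 0.42 - 0.0025 * (SBP - 100)   [decreasing]
diastolic decay power       p = 2.2  - 0.02   * (DBP - 50)    [decreasing]
dicrotic wave amplitude     a = 0.04 + 0.002  * (DBP - 50)    [increasing]
mean interbeat interval     m = 1.05 - 0.004  * (SBP - 100) s [decreasing]
IBI jitter SD (default)     j = 0.008 + 0.0004 * (DBP - 50) s [increasing]
==========================  =============================================

A smaller decay power p makes the diastolic limb fall more slowly, so
diastolic fractional widths increase with DBP. The ABP channel is the same
normalised template mapped to ``dbp + (sbp - dbp) * template`` so that every
beat's peak equals the assigned SBP and every trough the assigned DBP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigError, DomainError
from .signal_io import BPReference, SampledSignal, SignalKind, SubjectRecord

# coupling constants (see module docstring) -- not tunable per run
_U_BASE, _U_SLOPE = 0.42, -0.0025          # upstroke fraction vs SBP
_P_BASE, _P_SLOPE = 2.2, -0.02             # decay power vs DBP
_A_BASE, _A_SLOPE = 0.04, 0.002            # dicrotic amplitude vs DBP
_M_BASE, _M_SLOPE = 1.05, -0.004           # mean IBI (s) vs SBP
_J_BASE, _J_SLOPE = 0.008, 0.0004          # IBI jitter SD (s) vs DBP


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings; defaults mirror the target datasets
    (8-min records at 125 Hz, SBP 105-152 mmHg, DBP 54-73 mmHg)."""

    n_subjects: int = 25
    duration_s: float = 480.0
    fs: float = 125.0
    sbp_range: tuple[float, float] = (105.0, 152.0)
    dbp_range: tuple[float, float] = (54.0, 73.0)
    mean_hr_range: tuple[float, float] = (55.0, 75.0)  # informational; HR follows SBP coupling
    lf_amp: float = 0.02
    hf_amp: float = 0.015
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    noise_sd: float = 0.0
    ibi_jitter_sd: float | None = None  # None -> DBP-coupled default
    dicrotic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("sbp_range", self.sbp_range),
                               ("dbp_range", self.dbp_range),
                               ("mean_hr_range", self.mean_hr_range)):
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered lo < hi, got {(lo, hi)}")
        if not self.dbp_range[1] < self.sbp_range[0]:
            raise ConfigError("dbp_range upper bound must stay below sbp_range lower bound")
        if self.fs < 50:
            raise ConfigError(f"fs must be >= 50 Hz, got {self.fs}")
        if self.duration_s < 60:
            raise ConfigError(f"duration_s must be >= 60 s, got {self.duration_s}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: assigned BP, beat timing, template params."""

    sbp: float
    dbp: float
    onset_times: np.ndarray          # beat onsets, s, strictly increasing
    peak_times: np.ndarray           # systolic peak per beat, s
    ibis: np.ndarray                 # per-beat interbeat interval, s
    template_params: dict = field(default_factory=dict)


def _coupled_params(sbp: float, dbp: float, dicrotic: bool) -> dict:
    u = float(np.clip(_U_BASE + _U_SLOPE * (sbp - 100.0), 0.10, 0.48))
    p = float(np.clip(_P_BASE + _P_SLOPE * (dbp - 50.0), 0.8, 3.0))
    a = float(_A_BASE + _A_SLOPE * (dbp - 50.0)) if dicrotic else 0.0
    return {"upstroke_frac": u, "decay_power": p, "dicrotic_amp": a}


def synth_pulse_template(
    sbp: float, dbp: float, dicrotic: bool = True
) -> Callable[[np.ndarray], np.ndarray]:
    """Unit-amplitude pulse shape on phase [0, 1) coupled to (sbp, dbp).

    Returns a vectorised callable ``template(phase) -> amplitude`` that is
    C0-continuous, starts and ends at 0, and has its single dominant maximum
    (value 1) at the systolic-upstroke fraction.
    """
    if not sbp > dbp:
        raise DomainError(f"need sbp > dbp, got ({sbp}, {dbp})")
    prm = _coupled_params(sbp, dbp, dicrotic)
    u, p, a = prm["upstroke_frac"], prm["decay_power"], prm["dicrotic_amp"]

    def template(phase: np.ndarray) -> np.ndarray:
        s = np.asarray(phase, dtype=float) % 1.0
        out = np.empty_like(s)
        rising = s < u
        out[rising] = 0.5 * (1.0 - np.cos(np.pi * s[rising] / u))
        q = (s[~rising] - u) / (1.0 - u)
        decay = (0.5 * (1.0 + np.cos(np.pi * q))) ** p
        if a > 0.0:
            # broad, low-amplitude secondary wave on the diastolic limb
            decay = decay + a * np.exp(-0.5 * ((q - 0.50) / 0.18) ** 2) * np.sin(np.pi * q)
        out[~rising] = decay
        return out

    template.params = prm  # type: ignore[attr-defined]
    return template


def synth_ibi_sequence(
    config: SyntheticConfig,
    mean_ibi: float,
    seed: int,
    jitter_sd: float | None = None,
) -> np.ndarray:
    """Beat onset times with LF/HF-modulated interbeat intervals.

    ``IBI(k) = mean_ibi + lf_amp*sin(2*pi*lf_freq*t_k) +
    hf_amp*sin(2*pi*hf_freq*t_k) + N(0, jitter_sd^2)``, onsets are the
    cumulative sums. Deterministic given the seed.
    """
    if not 0.4 <= mean_ibi <= 1.5:
        raise ConfigError(f"mean_ibi must be in [0.4, 1.5] s, got {mean_ibi}")
    jitter = config.ibi_jitter_sd if jitter_sd is None else jitter_sd
    if jitter is None:
        jitter = 0.01
    rng = np.random.default_rng(seed)
    onsets = [0.0]
    t = 0.0
    while t < config.duration_s:
        ibi = (mean_ibi
               + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t)
               + config.hf_amp * np.sin(2 * np.pi * config.hf_freq * t)
               + (rng.normal(0.0, jitter) if jitter > 0 else 0.0))
        if ibi <= 0.25:
            raise ConfigError(
                "IBI modulation parameters produced an interval <= 0.25 s"
            )
        t += ibi
        onsets.append(t)
    return np.asarray(onsets)


def generate_subject(
    config: SyntheticConfig,
    sbp: float,
    dbp: float,
    seed: int,
    subject_id: str = "S000",
) -> tuple[SubjectRecord, GroundTruth]:
    """One coupled PPG+ABP record with its ground truth.

    The PPG is the pulse template resampled to each beat's interval plus
    additive Gaussian noise; the ABP is the same normalised waveform mapped
    to [dbp, sbp] mmHg, so its per-beat peak/trough equal the assigned BP.
    """
    lo, hi = config.sbp_range
    if not lo <= sbp <= hi:
        raise ConfigError(f"sbp {sbp} outside configured range {config.sbp_range}")
    lo, hi = config.dbp_range
    if not lo <= dbp <= hi:
        raise ConfigError(f"dbp {dbp} outside configured range {config.dbp_range}")

    prm = _coupled_params(sbp, dbp, config.dicrotic)
    mean_ibi = float(np.clip(_M_BASE + _M_SLOPE * (sbp - 100.0), 0.4, 1.5))
    jitter = (config.ibi_jitter_sd if config.ibi_jitter_sd is not None
              else _J_BASE + _J_SLOPE * (dbp - 50.0))
    onsets = synth_ibi_sequence(config, mean_ibi, seed, jitter_sd=jitter)
    ibis = np.diff(onsets)

    template = synth_pulse_template(sbp, dbp, config.dicrotic)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    # map every sample to its beat and in-beat phase
    beat = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(ibis) - 1)
    phase = np.clip((t - onsets[beat]) / ibis[beat], 0.0, 1.0 - 1e-12)
    shape = template(phase)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xABCD)))
    ppg_samples = shape.copy()
    if config.noise_sd > 0:
        ppg_samples = ppg_samples + rng.normal(0.0, config.noise_sd, size=n)
    abp_samples = dbp + (sbp - dbp) * shape

    ppg = SampledSignal(ppg_samples, fs=config.fs, kind=SignalKind.PPG)
    abp = SampledSignal(abp_samples, fs=config.fs, kind=SignalKind.ABP)
    reference = BPReference(sbp=sbp, dbp=dbp)
    record = SubjectRecord(id=subject_id, ppg=ppg, reference=reference, abp=abp)

    peak_times = onsets[:-1] + prm["upstroke_frac"] * ibis
    truth = GroundTruth(
        sbp=sbp, dbp=dbp,
        onset_times=onsets,
        peak_times=peak_times,
        ibis=ibis,
        template_params={**prm, "mean_ibi": mean_ibi, "ibi_jitter_sd": jitter},
    )
    return record, truth


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SubjectRecord], list[GroundTruth]]:
    """n_subjects coupled records; assigned BP drawn uniformly from the
    configured ranges; per-subject seeds spawned from the master seed."""
    master = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    sbps = assign_rng.uniform(*config.sbp_range, size=config.n_subjects)
    dbps = assign_rng.uniform(*config.dbp_range, size=config.n_subjects)
    records, truths = [], []
    for i in range(config.n_subjects):
        child_seed = int(np.random.SeedSequence((config.seed, i + 1)).generate_state(1)[0] % (2**31))
        rec, truth = generate_subject(
            config, float(sbps[i]), float(dbps[i]), seed=child_seed,
            subject_id=f"S{i:03d}",
        )
        records.append(rec)
        truths.append(truth)
    return records, truths


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with PPG noise and IBI jitter switched off."""
    return replace(config, noise_sd=0.0, ibi_jitter_sd=0.0)
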