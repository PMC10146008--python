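"""Shared fixtures: analytic pulses and small synthetic cohorts."""

import numpy as np
import pytest

import ppgbp as pb
from ppgbp.fiducials import PulseSegment
from ppgbp.pipeline import cohort_feature_table


@pytest.fixture
def triangle_segment() -> PulseSegment:
    """Asymmetric triangle: onset 0, peak 1 at t=0.2 s, back to 0 at 0.6 s."""
    fs = 1000.0
    t = np.arange(0, 0.6 + 0.5 / fs, 1 / fs)
    y = np.where(t <= 0.2, t / 0.2, (0.6 - t) / 0.4)
    return PulseSegment(samples=y, fs=fs, peak_offset=int(round(0.2 * fs)))


@pytest.fixture(scope="session")
def clean_subject():
    """Noiseless 120 s subject at (120, 70) mmHg with its ground truth."""
    cfg = pb.SyntheticConfig(n_subjects=1, duration_s=120, seed=3,
                             noise_sd=0.0, ibi_jitter_sd=0.0)
    return pb.generate_subject(cfg, 120.0, 70.0, seed=11)


@pytest.fixture(scope="session")
def cohort_table_40():
    """Feature table of a noiseless 40-subject cohort (360 s records)."""
    cfg = pb.SyntheticConfig(n_subjects=40, duration_s=360, seed=11,
                             noise_sd=0.0)
    records, truths = pb.generate_cohort(cfg)
    return cohort_feature_table(records), truths
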