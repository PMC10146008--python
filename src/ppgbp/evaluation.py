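"""Error metrics and Bland-Altman agreement statistics.

Errors are oriented estimate - reference. With e_i = y_i - x_i over n
subjects:

    ME  = mean(e_i)
    MAE = mean(|e_i|)
    SDE = sqrt(mean((e_i - mean(e))^2))      (population, n denominator)

Bland-Altman agreement uses bias = mean difference and 95% limits of
agreement bias +/- 1.96 * SD (population SD, matching the SDE convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError


@dataclass(frozen=True)
class ErrorSummary:
    me: float
    sde: float
    mae: float
    n: int


@dataclass(frozen=True)
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = None        # per-subject (pred+ref)/2, for plotting
    differences: np.ndarray = None


def _check(preds, refs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(preds, dtype=float)
    r = np.asarray(refs, dtype=float)
    if p.shape != r.shape or p.size < 2:
        raise SchemaError("preds and refs must have equal length >= 2")
    return p, r


def error_summary(preds: np.ndarray, refs: np.ndarray) -> ErrorSummary:
    """ME / SDE / MAE of estimate-minus-reference errors."""
    p, r = _check(preds, refs)
    e = p - r
    return ErrorSummary(
        me=float(np.mean(e)),
        sde=float(np.std(e)),
        mae=float(np.mean(np.abs(e))),
        n=e.size,
    )


def bland_altman(preds: np.ndarray, refs: np.ndarray) -> AgreementStats:
    """Bias and 95% limits of agreement of estimate-minus-reference."""
    p, r = _check(preds, refs)
    d = p - r
    bias = float(np.mean(d))
    sd = float(np.std(d))
    return AgreementStats(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=d.size,
        means=(p + r) / 2.0,
        differences=d,
    )


def results_table(
    methods: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
) -> pd.DataFrame:
    """One row per method with (ME, SDE, MAE) column groups for SBP and DBP.

    ``methods`` maps method name -> {"sbp": (preds, refs), "dbp": (preds,
    refs)}; every method must cover the same subjects (checked by length).
    """
    rows = {}
    n_ref: int | None = None
    for name, targets in methods.items():
        row = {}
        for target in ("sbp", "dbp"):
            preds, refs = targets[target]
            preds = np.asarray(preds, dtype=float)
            if n_ref is None:
                n_ref = preds.size
            elif preds.size != n_ref:
                raise AlignmentError(
                    f"method {name!r} covers {preds.size} subjects, "
                    f"expected {n_ref}"
                )
            s = error_summary(preds, refs)
            prefix = target.upper()
            row[f"{prefix}_ME"] = s.me
            row[f"{prefix}_SDE"] = s.sde
            row[f"{prefix}_MAE"] = s.mae
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
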