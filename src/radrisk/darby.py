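"""Darby linear excess-relative-risk model for major coronary events.

The rate of major coronary events after breast radiotherapy increases
linearly with mean heart dose, without threshold:

    ERR = 0.074 per Gy * D_mean
    cumulative risk = baseline risk * (1 + ERR)

ERR is kept as a dimensionless fraction internally; percent formatting
belongs to the reporting layer.
"""

from __future__ import annotations

import warnings

__all__ = ["DARBY_SLOPE_PER_GY", "err_mce", "cumulative_risk", "err_from_risks"]

#: Excess relative risk of major coronary events per Gy mean heart dose.
DARBY_SLOPE_PER_GY = 0.074


def err_mce(mean_heart_dose: float, slope: float = DARBY_SLOPE_PER_GY) -> float:
    """Excess relative risk of a major coronary event for a mean heart dose."""
    if mean_heart_dose < 0:
        raise ValueError(f"mean heart dose must be >= 0, got {mean_heart_dose}")
    if not slope > 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    return slope * mean_heart_dose


def cumulative_risk(baseline: float, err: float) -> float:
    """Lifetime cumulative risk baseline*(1+ERR), clamped to 1 with a warning."""
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline risk must be in [0, 1], got {baseline}")
    if err < -1.0:
        raise ValueError(f"ERR must be >= -1, got {err}")
    risk = baseline * (1.0 + err)
    if risk > 1.0:
        warnings.warn("cumulative risk exceeds 1; clamped", stacklevel=2)
        return 1.0
    return risk


def err_from_risks(baseline: float, cumulative: float) -> float:
    """Back-calculate ERR from baseline and cumulative risk (inverse model)."""
    if not baseline > 0:
        raise ValueError(f"baseline risk must be > 0, got {baseline}")
    if cumulative < 0:
        raise ValueError(f"cumulative risk must be >= 0, got {cumulative}")
    return cumulative / baseline - 1.0
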