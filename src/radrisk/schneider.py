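"""Schneider secondary-cancer excess absolute risk models.

Two regimes share one parameterisation fitted by Schneider and colleagues
to atomic-bomb-survivor (low-dose) and Hodgkin-lymphoma radiotherapy
(high-dose) data:

* out-of-field, low dose — linear no-threshold (LNT):
  ``EAR = delta * D * mu(age_x, age_a)`` with D the mean organ dose;
* in-field, radiotherapeutic doses — the full mechanistic model replaces
  D by the risk-equivalent dose RED(D), which bends the response downwards
  through linear-quadratic cell kill and partial repopulation between
  fractions (parameter R in [0, 1], 0 = no regeneration, 1 = complete).

The age modifier is ``mu = exp(gamma_e*(age_x - 30) + gamma_a*ln(age_a/70))``
(reference: exposure at 30, attained age 70). EAR is reported per
10,000 person-years throughout, the native unit of the initial slope delta.

In the low-dose limit RED(D) -> D, so the full model degenerates to LNT;
the sign of the R^2 exponential in the repopulation bracket is fixed by
exactly this limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose import DEFAULT_ALPHA_BETA, DoseVolumeHistogram, FractionationScheme

__all__ = [
    "SchneiderParams",
    "AgePair",
    "age_modifier",
    "ear_lnt",
    "alpha_prime",
    "red",
    "organ_equivalent_dose",
    "ear_full",
]

#: Threshold below/above which the analytic R -> 0 / R -> 1 limits replace
#: the general repopulation bracket (numerically singular at R = 0, 1).
_R_EPS = 1e-6


@dataclass(frozen=True)
class SchneiderParams:
    """Organ-specific parameters of the Schneider EAR models.

    delta     initial slope, per (10,000 person-years * Gy)
    gamma_e   age-at-exposure modifier, per year
    gamma_a   attained-age exponent (dimensionless)
    alpha_lq  linear-quadratic alpha, per Gy
    repop     repopulation/repair capacity R in [0, 1]
    ab        alpha/beta ratio in Gy used to derive beta = alpha / (a/b)
    """

    organ: str
    delta: float
    gamma_e: float
    gamma_a: float
    alpha_lq: float
    repop: float
    ab: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not self.alpha_lq > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha_lq}")
        if not 0.0 <= self.repop <= 1.0:
            raise ValueError(f"repopulation parameter R must be in [0, 1], got {self.repop}")
        if not self.ab > 0:
            raise ValueError(f"alpha/beta must be > 0, got {self.ab}")

    @property
    def beta_lq(self) -> float:
        """LQ beta in Gy^-2, derived as alpha / (alpha/beta)."""
        return self.alpha_lq / self.ab


@dataclass(frozen=True)
class AgePair:
    """Age at exposure and attained age, in years."""

    age_x: float
    age_a: float

    def __post_init__(self) -> None:
        if not self.age_x > 0:
            raise ValueError(f"age at exposure must be > 0, got {self.age_x}")
        if self.age_a < self.age_x:
            raise ValueError("attained age must be >= age at exposure")


def age_modifier(ages: AgePair, params: SchneiderParams) -> float:
    """Exponential age modifier mu; equals 1 at the reference ages (30, 70)."""
    return math.exp(
        params.gamma_e * (ages.age_x - 30.0)
        + params.gamma_a * math.log(ages.age_a / 70.0)
    )


def ear_lnt(mean_dose: float, ages: AgePair, params: SchneiderParams) -> float:
    """Linear no-threshold EAR from a mean organ dose, per 10,000 PY."""
    if mean_dose < 0:
        raise ValueError(f"mean_dose must be >= 0, got {mean_dose}")
    return params.delta * mean_dose * age_modifier(ages, params)


def alpha_prime(
    point_dose: float, scheme: FractionationScheme, params: SchneiderParams
) -> float:
    """Fractionation-adjusted LQ slope alpha' = alpha + beta*(d_T/D_T)*D.

    Under proportional fractionation a voxel at local total dose D receives
    D * d_T/D_T per fraction, so alpha' * D is exactly alpha * BED of that
    voxel.
    """
    if point_dose < 0:
        raise ValueError(f"point_dose must be >= 0, got {point_dose}")
    if not scheme.total_dose > 0:
        raise ValueError("prescribed total dose must be > 0")
    return params.alpha_lq + params.beta_lq * (
        scheme.dose_per_fraction / scheme.total_dose
    ) * point_dose


def red(point_dose, alpha_p: float, repop: float):
    """Risk-equivalent dose RED(D) of the full mechanistic model, in Gy.

    General form (0 < R < 1):

        RED = e^(-a'D) / (a'R) * [1 - 2R + R^2 e^(+a'D)
                                  - (1-R)^2 e^(-a'D R/(1-R))]

    with the analytic limits substituted near the boundary: R -> 0 gives the
    pure cell-kill (bell) form D*e^(-a'D), R -> 1 the plateau form
    (1 - e^(-a'D))/a'. RED(D) <= D with RED(D)/D -> 1 as D -> 0. Accepts a
    scalar or an array of doses.
    """
    if not alpha_p > 0:
        raise ValueError(f"alpha' must be > 0, got {alpha_p}")
    if not 0.0 <= repop <= 1.0:
        raise ValueError(f"repopulation parameter R must be in [0, 1], got {repop}")
    D = np.asarray(point_dose, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    x = alpha_p * D
    if repop <= _R_EPS:
        out = D * np.exp(-x)
    elif repop >= 1.0 - _R_EPS:
        out = -np.expm1(-x) / alpha_p
    else:
        R = repop
        bracket = (
            1.0
            - 2.0 * R
            + R * R * np.exp(x)
            - (1.0 - R) ** 2 * np.exp(-x * R / (1.0 - R))
        )
        out = np.exp(-x) / (alpha_p * R) * bracket
    out = np.where(D == 0.0, 0.0, out)  # cancellation can leave ~1e-16 residue
    return out if out.ndim else float(out)


def _bin_alpha_prime(
    mids: np.ndarray,
    scheme: FractionationScheme | None,
    params: SchneiderParams,
) -> np.ndarray:
    """Per-bin alpha' for a summed or single-course DVH.

    ``scheme is None`` marks an EQD2-scale summed plan: alpha'*D accumulates
    over courses as alpha * BED, and on the EQD2 scale BED = D*(1 + 2/(a/b)),
    i.e. a constant effective alpha' = alpha * (1 + 2/(a/b)).
    """
    if scheme is None:
        return np.full_like(mids, params.alpha_lq * (1.0 + 2.0 / params.ab))
    return params.alpha_lq + params.beta_lq * (
        scheme.dose_per_fraction / scheme.total_dose
    ) * mids


def organ_equivalent_dose(
    dvh: DoseVolumeHistogram,
    scheme: FractionationScheme | None,
    params: SchneiderParams,
) -> float:
    """Volume-weighted mean RED over the DVH (the organ equivalent dose), Gy."""
    mids = dvh.bin_midpoints
    vols = dvh.diff_volume
    mask = (mids > 0) & (vols > 0)
    if not mask.any():
        return 0.0
    ap = _bin_alpha_prime(mids[mask], scheme, params)
    reds = np.array(
        [red(m, a, params.repop) for m, a in zip(mids[mask], ap)]
    )
    return float(np.dot(vols[mask], reds))


def ear_full(
    dvh: DoseVolumeHistogram,
    scheme: FractionationScheme | None,
    ages: AgePair,
    params: SchneiderParams,
) -> float:
    """Full-model EAR per 10,000 PY: delta * mu * sum_i v_i * RED(D_i)."""
    return params.delta * age_modifier(ages, params) * organ_equivalent_dose(
        dvh, scheme, params
    )
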