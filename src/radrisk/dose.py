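"""Dose data model, linear-quadratic dose conversion and plan summation.

Treatment courses with different fractionation schemes are made comparable
through the biologically effective dose of the linear-quadratic model,

    BED = n * d * (1 + d / (alpha/beta)),

with ``n`` fractions of ``d`` Gy each, and reported as the equivalent total
dose in 2-Gy fractions (EQD2, often written "BED2"),

    EQD2 = BED / (1 + 2 / (alpha/beta)).

For late-responding normal tissue alpha/beta = 3 Gy is used throughout.
Multi-course plans are summed voxelwise in BED space on pre-aligned grids;
registration is an input contract, not performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DEFAULT_ALPHA_BETA",
    "AlphaBetaRatio",
    "FractionationScheme",
    "DoseDistribution",
    "DoseVolumeHistogram",
    "bed",
    "eqd2",
    "sum_courses",
    "dvh_from_distribution",
    "dose_metrics",
]

#: Late-responding tissue alpha/beta ratio in Gy used as default everywhere.
DEFAULT_ALPHA_BETA = 3.0


@dataclass(frozen=True)
class AlphaBetaRatio:
    """Tissue alpha/beta ratio of the linear-quadratic model, in Gy."""

    value: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"alpha/beta ratio must be > 0, got {self.value}")


def _as_ab(ab: "AlphaBetaRatio | float | None") -> AlphaBetaRatio:
    if ab is None:
        return AlphaBetaRatio()
    if isinstance(ab, AlphaBetaRatio):
        return ab
    return AlphaBetaRatio(float(ab))


@dataclass(frozen=True)
class FractionationScheme:
    """A course of ``n_fractions`` fractions of ``dose_per_fraction`` Gy."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if not self.dose_per_fraction > 0:
            raise ValueError(f"dose_per_fraction must be > 0, got {self.dose_per_fraction}")

    @property
    def total_dose(self) -> float:
        """Prescribed total dose D = n * d in Gy."""
        return self.n_fractions * self.dose_per_fraction


#: Reference scheme of the EQD2 scale: 2 Gy per fraction.
EQD2_REFERENCE_DOSE_PER_FRACTION = 2.0


@dataclass(frozen=True)
class DoseDistribution:
    """Per-organ voxel dose vector (Gy) for one course on a uniform grid.

    ``scheme is None`` marks a distribution already expressed on the EQD2
    scale (every voxel notionally delivered in 2-Gy fractions), as produced
    by :func:`sum_courses`.
    """

    organ: str
    voxel_doses: np.ndarray
    voxel_volume: float
    scheme: FractionationScheme | None

    def __post_init__(self) -> None:
        doses = np.asarray(self.voxel_doses, dtype=float)
        object.__setattr__(self, "voxel_doses", doses)
        if doses.ndim != 1 or doses.size == 0:
            raise ValueError("voxel_doses must be a non-empty 1-D vector")
        if np.any(doses < 0):
            raise ValueError("voxel doses must be non-negative")
        if not self.voxel_volume > 0:
            raise ValueError(f"voxel_volume must be > 0, got {self.voxel_volume}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_doses.size)

    @property
    def mean_dose(self) -> float:
        """Volume-mean dose in Gy (uniform voxel volume)."""
        return float(self.voxel_doses.mean())

    def voxel_fraction_doses(self) -> np.ndarray:
        """Per-voxel dose per fraction under proportional fractionation.

        Every voxel is treated in the course's n fractions, so the local
        fraction dose is D_voxel / n (equivalently d_T * D_voxel / D_T).
        For an EQD2-scale distribution (``scheme is None``) the reference
        2 Gy per fraction applies to every voxel.
        """
        if self.scheme is None:
            return np.full_like(self.voxel_doses, EQD2_REFERENCE_DOSE_PER_FRACTION)
        return self.voxel_doses / self.scheme.n_fractions

    def voxel_bed(self, ab: AlphaBetaRatio | float | None = None) -> np.ndarray:
        """Voxelwise BED vector for this course."""
        ab = _as_ab(ab)
        return self.voxel_doses * (1.0 + self.voxel_fraction_doses() / ab.value)


def bed(
    total_dose: float,
    scheme: FractionationScheme,
    ab: AlphaBetaRatio | float | None = None,
) -> float:
    """Biologically effective dose of ``total_dose`` Gy delivered per ``scheme``.

    When ``total_dose`` differs from the scheme's prescribed total (e.g. a
    voxel off prescription), the fraction dose is re-derived as
    ``total_dose / n_fractions`` (proportional fractionation). The
    protracted-irradiation (incomplete repair) correction is deliberately
    absent: for high-dose-rate delivery it is negligible.
    """
    ab = _as_ab(ab)
    if total_dose < 0:
        raise ValueError(f"total_dose must be >= 0, got {total_dose}")
    d = total_dose / scheme.n_fractions
    return total_dose * (1.0 + d / ab.value)


def eqd2(bed_value: float, ab: AlphaBetaRatio | float | None = None) -> float:
    """Equivalent total dose in 2-Gy fractions for a given BED.

    Inverse of :func:`bed` on a 2-Gy-per-fraction course: a course delivered
    at 2 Gy per fraction maps to its own physical total dose.
    """
    ab = _as_ab(ab)
    if bed_value < 0:
        raise ValueError(f"bed_value must be >= 0, got {bed_value}")
    return bed_value / (1.0 + 2.0 / ab.value)


def sum_courses(
    distributions: Sequence[DoseDistribution],
    ab: AlphaBetaRatio | float | None = None,
    mode: Literal["eqd2", "physical"] = "eqd2",
) -> DoseDistribution:
    """Sum pre-aligned per-course dose distributions of one organ.

    In ``"eqd2"`` mode (default) each voxel's per-course dose is converted
    to BED with that course's local fraction dose, the BEDs are summed and
    the result is mapped back to the EQD2 scale. In ``"physical"`` mode the
    voxel doses are summed directly. The returned distribution carries
    ``scheme=None`` (EQD2 reference) in the former case; in physical mode
    the scheme is retained only if all courses share one scheme.
    """
    ab = _as_ab(ab)
    if not distributions:
        raise ValueError("no distributions to sum")
    first = distributions[0]
    for d in distributions[1:]:
        if d.organ != first.organ:
            raise ValueError(f"organ mismatch: {d.organ!r} vs {first.organ!r}")
        if d.n_voxels != first.n_voxels or d.voxel_volume != first.voxel_volume:
            raise ValueError("distributions must share a common voxel grid")
    if mode == "eqd2":
        total_bed = np.sum([d.voxel_bed(ab) for d in distributions], axis=0)
        doses = total_bed / (1.0 + 2.0 / ab.value)
        scheme: FractionationScheme | None = None
    elif mode == "physical":
        doses = np.sum([d.voxel_doses for d in distributions], axis=0)
        schemes = {d.scheme for d in distributions}
        scheme = schemes.pop() if len(schemes) == 1 else None
    else:
        raise ValueError(f"unknown summation mode {mode!r}")
    return DoseDistribution(
        organ=first.organ, voxel_doses=doses, voxel_volume=first.voxel_volume, scheme=scheme
    )


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Differential dose-volume histogram with half-open bins [edge_i, edge_{i+1}).

    ``diff_volume`` holds fractional volumes (dimensionless, summing to 1);
    percentages appear only at the reporting layer. Bin doses are taken at
    bin midpoints.
    """

    organ: str
    bin_edges: np.ndarray
    diff_volume: np.ndarray

    representation: str = field(default="differential")

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.diff_volume, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "diff_volume", vols)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges needs at least two edges")
        if edges[0] != 0.0:
            raise ValueError("first bin edge must be 0 Gy")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if vols.shape != (edges.size - 1,):
            raise ValueError("diff_volume length must equal number of bins")
        if np.any(vols < 0):
            raise ValueError("differential volumes must be non-negative")
        if abs(vols.sum() - 1.0) > 1e-9:
            raise ValueError(f"differential volumes must sum to 1, got {vols.sum()!r}")
        if self.representation != "differential":
            raise ValueError("internal representation is always differential")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_dose(self) -> float:
        """Dmean = sum_i v_i * D_i over bin midpoints, in Gy."""
        return float(np.dot(self.diff_volume, self.bin_midpoints))

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative DVH sampled at the bin edges.

        Returns ``(dose, volume_fraction)`` where volume_fraction[j] is the
        fractional volume receiving at least dose[j]; it is 1 at dose 0 and
        monotone non-increasing.
        """
        cum = np.concatenate(([self.diff_volume.sum()], self.diff_volume.sum() - np.cumsum(self.diff_volume)))
        cum = np.clip(cum, 0.0, None)
        cum[0] = 1.0
        return self.bin_edges.copy(), cum


def dvh_from_distribution(dist: DoseDistribution, bin_width: float = 0.1) -> DoseVolumeHistogram:
    """Bin a voxel dose vector into a differential DVH.

    Half-open bins of ``bin_width`` Gy starting at 0 and covering the
    maximum voxel dose; volume is conserved exactly.
    """
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    doses = dist.voxel_doses
    n_bins = int(np.floor(doses.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    # guard against doses falling exactly on the last (closed) numpy edge
    assert counts.sum() == doses.size
    return DoseVolumeHistogram(
        organ=dist.organ, bin_edges=edges, diff_volume=counts / doses.size
    )


def _hot_cumulative(dvh: DoseVolumeHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Hottest-first cumulative volume at occupied bin midpoints (ascending dose)."""
    occupied = dvh.diff_volume > 0
    mids = dvh.bin_midpoints[occupied]
    vols = dvh.diff_volume[occupied]
    # cumulative volume receiving >= each midpoint dose
    cum = vols[::-1].cumsum()[::-1]
    return mids, cum


def dose_metrics(
    dvh: DoseVolumeHistogram,
    v_thresholds: Iterable[float] = (20.0,),
    d_percents: Iterable[float] = (1.0,),
) -> dict[str, float]:
    """Standard DVH plan metrics.

    Returns ``Dmean`` (Gy), ``V{x}Gy`` — the percent of organ volume
    receiving at least x Gy — and ``D{y}%`` — the minimum dose (Gy) received
    by the hottest y percent of the volume, interpolated linearly on the
    hottest-first cumulative curve over bin midpoints.
    """
    metrics = {"Dmean": dvh.mean_dose}
    mids, cum = _hot_cumulative(dvh)
    for x in v_thresholds:
        v = float(cum[np.searchsorted(mids, x)]) if x <= mids[-1] else 0.0
        if x <= mids[0]:
            v = 1.0
        metrics[f"V{x:g}Gy"] = 100.0 * v
    for y in d_percents:
        if not 0.0 < y <= 100.0:
            raise ValueError(f"volume percentage must be in (0, 100], got {y}")
        frac = y / 100.0
        if frac <= cum[-1]:
            d = mids[-1]
        elif frac >= cum[0]:
            d = mids[0]
        else:
            # cum is decreasing in dose; interpolate dose as function of volume
            d = float(np.interp(frac, cum[::-1], mids[::-1]))
        metrics[f"D{y:g}%"] = float(d)
    return metrics
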