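"""End-to-end cohort risk pipeline and scenario statistics.

Per patient and organ the pipeline composes the dose, NTCP and risk models:
courses are summed on the EQD2 scale, binned to a DVH, and routed to the
model appropriate for the organ's dose regime — the full Schneider model on
the summed distribution for in-field organs (ipsilateral lung), the linear
no-threshold model on a mean organ dose for out-of-field organs
(contralateral lung and breast), the Darby linear excess-relative-risk model
for the heart, and LKB NTCP for the lung pneumonitis endpoints (whole lung =
pooled ipsilateral + contralateral voxels).

Scenario comparisons follow small-cohort practice: a Shapiro-Wilk normality
check on each group gates the choice between Welch's unequal-variance t-test
(both groups normal) and the Mann-Whitney U test; raw two-sided p-values are
reported (a Holm-corrected column is emitted as a clearly labelled
extension).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .darby import err_mce
from .dose import DoseDistribution, dose_metrics, dvh_from_distribution, sum_courses
from .io import read_dose_distribution, read_tld_sets
from .lkb import eud, ntcp
from .params import RiskParameterSet, load_default_parameters
from .schneider import AgePair, ear_full, ear_lnt
from .synthetic import IN_FIELD_ORGANS, ORGANS, OUT_OF_FIELD_ORGANS
from .tld import mean_organ_dose, outlier_excluded_mean

__all__ = [
    "CohortSummary",
    "PairwiseTestResult",
    "summarize",
    "compare_groups",
    "pooled_mean",
    "patient_risk_profile",
    "run_study",
    "compare_scenarios",
    "build_report",
    "format_cell",
]

#: Schneider parameter row used for each organ label.
SCHNEIDER_ORGAN = {
    "lung_ipsi": "lung",
    "lung_contra": "lung",
    "lung_whole": "lung",
    "breast_contra": "breast",
}

#: Default reporting ages: exposure at 55, attained ages 75 and 95.
DEFAULT_AGES = (AgePair(55.0, 75.0), AgePair(55.0, 95.0))


@dataclass(frozen=True)
class CohortSummary:
    """Boxplot-style summary of one group of values."""

    group: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def summarize(values: Sequence[float], group: str = "") -> CohortSummary:
    """Mean/SD, range, quartiles, 1.5-IQR whiskers and outliers of a group."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return CohortSummary(
        group=group,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        minimum=float(x.min()),
        maximum=float(x.max()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(x[(x < lo_fence) | (x > hi_fence)])),
    )


@dataclass(frozen=True)
class PairwiseTestResult:
    """Outcome of one normality-gated two-sample comparison."""

    group_a: str
    group_b: str
    test: str  # welch_t | mann_whitney
    p_value: float
    significant: bool  # at 0.05


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = 0.05,
) -> PairwiseTestResult:
    """Normality-gated unpaired two-sample test.

    Shapiro-Wilk at 0.05 on each group; if both pass, Welch's t-test,
    otherwise the Mann-Whitney U test (tie-corrected normal approximation).
    Degenerate constant groups cannot be tested for normality and fall to
    the Mann-Whitney branch with a warning. Two-sided p throughout.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0.0:
            warnings.warn("constant group; treating as non-normal", stacklevel=3)
            return False
        return stats.shapiro(x).pvalue > 0.05

    if _normal(a) and _normal(b):
        test = "welch_t"
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test = "mann_whitney"
        if np.ptp(np.concatenate([a, b])) == 0.0:
            p = 1.0  # identical constant groups: maximal p
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    p = min(p, 1.0)
    return PairwiseTestResult(label_a, label_b, test, p, bool(p < alpha))


def pooled_mean(group_means: Sequence[tuple[float, int]]) -> float:
    """Size-weighted pooled mean of per-group means: sum(n*m) / sum(n)."""
    if not group_means:
        raise ValueError("no groups to pool")
    total_n = sum(n for _, n in group_means)
    if total_n <= 0:
        raise ValueError("group sizes must be >= 1")
    return sum(m * n for m, n in group_means) / total_n


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (reporting extension)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def patient_risk_profile(
    courses_by_organ: Mapping[str, Mapping[str, DoseDistribution]],
    params: RiskParameterSet | None = None,
    ages: Iterable[AgePair] = DEFAULT_AGES,
    tld_mean_doses: Mapping[str, float] | None = None,
    bin_width: float = 0.1,
) -> dict[str, dict[str, float]]:
    """Per-organ risk record for one patient.

    For every organ the courses are summed twice: physically, for the plan
    dose statistics (Dmean, V20Gy, D1%) and the Darby ERR, whose slope is
    calibrated on physical mean heart dose; and on the EQD2 scale
    (biologically accumulated "BED2" dose) for the LKB EUD/NTCP endpoints
    and the full-model EAR of in-field organs. Out-of-field organs get the
    LNT EAR from ``tld_mean_doses`` when provided (falling back to the
    physical summed organ Dmean). A whole-lung record is derived by pooling
    the two lung voxel vectors. Missing organs are simply absent from the
    result, never imputed.
    """
    params = params or load_default_parameters()
    ages = tuple(ages)
    summed_phys: dict[str, DoseDistribution] = {}
    summed_eqd2: dict[str, DoseDistribution] = {}
    for organ in sorted(courses_by_organ):
        courses = [courses_by_organ[organ][k] for k in sorted(courses_by_organ[organ])]
        summed_phys[organ] = sum_courses(courses, params.alpha_beta, mode="physical")
        summed_eqd2[organ] = sum_courses(courses, params.alpha_beta, mode="eqd2")
    if "lung_ipsi" in summed_phys and "lung_contra" in summed_phys:
        for summed in (summed_phys, summed_eqd2):
            a, b = summed["lung_ipsi"], summed["lung_contra"]
            if a.voxel_volume == b.voxel_volume:
                summed["lung_whole"] = DoseDistribution(
                    organ="lung_whole",
                    voxel_doses=np.concatenate([a.voxel_doses, b.voxel_doses]),
                    voxel_volume=a.voxel_volume,
                    scheme=None if summed is summed_eqd2 else a.scheme,
                )

    profile: dict[str, dict[str, float]] = {}
    for organ, dist in summed_phys.items():
        rec = dose_metrics(dvh_from_distribution(dist, bin_width))
        rec["Dmean"] = dist.mean_dose  # voxel-exact, no binning offset
        if organ in SCHNEIDER_ORGAN:
            sp = params.schneider_for(SCHNEIDER_ORGAN[organ])
            dist_e = summed_eqd2[organ]
            dvh_e = dvh_from_distribution(dist_e, bin_width)
            if organ in ("lung_ipsi", "lung_whole"):
                for endpoint in params.lkb_endpoints("lung"):
                    lp = params.lkb_for("lung", endpoint)
                    e = eud(dvh_e, lp.n_volume)
                    rec[f"EUD_{endpoint}"] = e
                    rec[f"NTCP_{endpoint}"] = ntcp(e, lp)
            if organ in IN_FIELD_ORGANS or organ == "lung_whole":
                for ap in ages:
                    rec[f"EAR_a{ap.age_a:g}"] = ear_full(dvh_e, dist_e.scheme, ap, sp)
            else:
                mean_dose = (
                    tld_mean_doses[organ]
                    if tld_mean_doses and organ in tld_mean_doses
                    else rec["Dmean"]
                )
                for ap in ages:
                    rec[f"EAR_a{ap.age_a:g}"] = ear_lnt(mean_dose, ap, sp)
        if organ == "heart":
            rec["ERR"] = err_mce(rec["Dmean"], params.darby_slope)
        profile[organ] = rec
    return profile


# metrics carried into the scenario comparison/report stage, per organ
REPORT_METRICS = {
    "heart": ("Dmean", "ERR"),
    "lung_ipsi": (
        "Dmean", "V20Gy",
        "EUD_symptomatic_pneumonitis", "NTCP_symptomatic_pneumonitis",
        "EAR_a75", "EAR_a95",
    ),
    "lung_whole": (
        "Dmean", "V20Gy",
        "NTCP_symptomatic_pneumonitis", "NTCP_radiation_pneumonitis_g2",
    ),
    "lung_contra": ("Dmean", "EAR_a75", "EAR_a95"),
    "breast_contra": ("Dmean", "D1%", "EAR_a75", "EAR_a95"),
}


def run_study(
    data_dir: str | Path,
    params: RiskParameterSet | None = None,
    ages: Iterable[AgePair] = DEFAULT_AGES,
    bin_width: float = 0.1,
    exclude_tld_outliers: bool = True,
) -> dict[str, pd.DataFrame]:
    """Compute all per-patient and TLD-based risks for a generated dataset.

    Returns ``{"patients": ..., "tld": ...}``: one row per (scenario,
    patient, organ) with dose and risk metrics, and one row per TLD setup
    (scenario, breast size, organ) with full-course mean organ dose (with
    and without the largest-reading outlier when it dominates) and LNT EARs.
    """
    data_dir = Path(data_dir)
    params = params or load_default_parameters()
    ages = tuple(ages)

    rows = []
    for scen_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        for patient_dir in sorted(scen_dir.iterdir()):
            courses_by_organ: dict[str, dict[str, DoseDistribution]] = {}
            for f in sorted(patient_dir.glob("*.csv")):
                organ, _, course = f.stem.rpartition("_")
                courses_by_organ.setdefault(organ, {})[course] = read_dose_distribution(f)
            profile = patient_risk_profile(
                courses_by_organ, params, ages, bin_width=bin_width
            )
            for organ, rec in profile.items():
                rows.append(
                    {"scenario": scen_dir.name, "patient": patient_dir.name, "organ": organ, **rec}
                )
    patients = pd.DataFrame(rows).sort_values(["scenario", "patient", "organ"]).reset_index(drop=True)

    tld_rows = []
    tld_path = data_dir / "tld_readings.csv"
    if tld_path.exists():
        for m in read_tld_sets(tld_path):
            res = mean_organ_dose(m)
            dose = res.mean_dose
            # a reading >= 5x the median of the others marks a near-field outlier
            others = np.delete(m.readings, int(np.argmax(m.readings)))
            has_outlier = m.readings.max() >= 5.0 * np.median(others)
            dose_no_outlier = dose
            if has_outlier:
                dose_no_outlier = outlier_excluded_mean(
                    m, [int(np.argmax(m.readings))]
                ).mean_dose
            used = dose_no_outlier if (exclude_tld_outliers and has_outlier) else dose
            rec = {
                "scenario": m.scenario,
                "breast_size": m.breast_size,
                "organ": m.organ,
                "mean_dose": dose,
                "mean_dose_no_outlier": dose_no_outlier,
                "outlier_detected": has_outlier,
            }
            if m.organ in SCHNEIDER_ORGAN and m.organ in OUT_OF_FIELD_ORGANS:
                sp = params.schneider_for(SCHNEIDER_ORGAN[m.organ])
                for ap in ages:
                    rec[f"EAR_a{ap.age_a:g}"] = ear_lnt(used, ap, sp)
            tld_rows.append(rec)
    tld = pd.DataFrame(tld_rows)
    if not tld.empty:
        tld = tld.sort_values(["scenario", "breast_size", "organ"]).reset_index(drop=True)
    return {"patients": patients, "tld": tld}


def compare_scenarios(
    patients: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise scenario comparisons for every reported (organ, metric)."""
    rows = []
    scenarios = sorted(patients["scenario"].unique())
    for organ, metrics in sorted(REPORT_METRICS.items()):
        sub = patients[patients["organ"] == organ]
        if sub.empty:
            continue
        for metric in metrics:
            if metric not in sub.columns:
                continue
            for i, sa in enumerate(scenarios):
                for sb in scenarios[i + 1 :]:
                    va = sub.loc[sub.scenario == sa, metric].dropna().to_numpy()
                    vb = sub.loc[sub.scenario == sb, metric].dropna().to_numpy()
                    if va.size < 3 or vb.size < 3:
                        continue
                    res = compare_groups(va, vb, sa, sb, alpha)
                    rows.append(
                        {"organ": organ, "metric": metric, **asdict(res)}
                    )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_holm"] = np.nan
        for (_, _), idx in frame.groupby(["organ", "metric"]).groups.items():
            frame.loc[idx, "p_holm"] = holm_correction(frame.loc[idx, "p_value"].tolist())
    return frame


def format_cell(values: Sequence[float], decimals: int = 1) -> str:
    """Table cell in ``mean ± SD (min – max)`` style at table precision."""
    s = summarize(values)
    f = f"{{:.{decimals}f}}"
    return (
        f"{f.format(s.mean)} ± {f.format(s.sd)} "
        f"({f.format(s.minimum)} – {f.format(s.maximum)})"
    )


# scale factors and rounding applied at the reporting layer only
_REPORT_SCALE = {"NTCP": (100.0, 1), "ERR": (100.0, 1), "EAR": (1.0, 0), "": (1.0, 1)}


def _scale_for(metric: str) -> tuple[float, int]:
    for prefix, sf in _REPORT_SCALE.items():
        if prefix and metric.startswith(prefix):
            return sf
    return _REPORT_SCALE[""]


def build_report(
    results: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Scenario summary tables in the study's reporting style.

    Produces ``dose_stats`` (Dmean/V20/D1% per organ), ``ntcp_err`` (NTCP
    and ERR in percent), ``ear`` (per 10,000 PY, integer precision),
    ``tld_doses``, the pairwise ``tests`` table and ``boxplots`` (numeric
    boxplot summaries). Cells are ``mean ± SD (min – max)``; deterministic
    row/column ordering; byte-identical on identical inputs.
    """
    patients = results["patients"]
    tld = results["tld"]
    scenarios = sorted(patients["scenario"].unique())

    def table_for(metric_filter) -> pd.DataFrame:
        rows = {}
        for organ, metrics in sorted(REPORT_METRICS.items()):
            sub = patients[patients["organ"] == organ]
            if sub.empty:
                continue
            for metric in metrics:
                if metric not in sub.columns or not metric_filter(metric):
                    continue
                scale, dec = _scale_for(metric)
                row = {}
                for sc in scenarios:
                    vals = sub.loc[sub.scenario == sc, metric].dropna().to_numpy() * scale
                    if vals.size:
                        row[sc] = format_cell(vals, dec)
                if row:
                    rows[(organ, metric)] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index = pd.MultiIndex.from_tuples(frame.index, names=["organ", "metric"]) if len(frame) else frame.index
        return frame

    dose_stats = table_for(lambda m: m.startswith(("Dmean", "V", "D1", "EUD")))
    ntcp_err = table_for(lambda m: m.startswith(("NTCP", "ERR")))
    ear = table_for(lambda m: m.startswith("EAR"))

    tld_rows = {}
    if not tld.empty:
        for (organ, size), grp in tld.groupby(["organ", "breast_size"]):
            row = {}
            for sc in scenarios:
                v = grp.loc[grp.scenario == sc, "mean_dose_no_outlier"]
                if len(v):
                    row[sc] = f"{v.iloc[0]:.1f}"
            tld_rows[(organ, size)] = row
    tld_doses = pd.DataFrame.from_dict(tld_rows, orient="index")
    if len(tld_doses):
        tld_doses.index = pd.MultiIndex.from_tuples(tld_doses.index, names=["organ", "breast_size"])

    box_rows = []
    for organ, metrics in sorted(REPORT_METRICS.items()):
        sub = patients[patients["organ"] == organ]
        for metric in metrics:
            if metric not in sub.columns:
                continue
            for sc in scenarios:
                vals = sub.loc[sub.scenario == sc, metric].dropna().to_numpy()
                if vals.size:
                    s = summarize(vals, sc)
                    box_rows.append({"organ": organ, "metric": metric, **asdict(s)})
    boxplots = pd.DataFrame(box_rows)
    if not boxplots.empty:
        boxplots["outliers"] = boxplots["outliers"].apply(lambda t: ";".join(f"{v:.6g}" for v in t))

    return {
        "dose_stats": dose_stats,
        "ntcp_err": ntcp_err,
        "ear": ear,
        "tld_doses": tld_doses,
        "tests": compare_scenarios(patients, alpha),
        "boxplots": boxplots,
    }
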