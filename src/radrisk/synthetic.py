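"""Seeded synthetic cohorts emulating the four breast-radiotherapy scenarios.

No clinical dose grids accompany the study this package models, so every
downstream stage is exercised on synthetic per-patient organ dose
distributions and phantom-style TLD readings with the cohort-level
statistical structure of the four scenarios (3D-CRT + sequential boost,
3D-CRT + brachytherapy, IMRT + brachytherapy, IMRT + SiB).

Realism is DVH-level, not spatial: voxel doses are exchangeable draws from a
three-component mixture — an in-field component near the prescription dose
(±5%), a penumbra component uniform between 20% and 80% of prescription, and
an exponential out-of-field tail — rescaled per patient so that the organ
mean dose follows a truncated-normal draw around the configured scenario
target. Brachytherapy boosts deposit only a small exponential-tail dose in
the organs at risk (steep Ir-192 falloff); teletherapy boosts add a scaled
copy of the in-field pattern; the SiB folds its boost into a single course
whose boost voxels simply carry the higher total dose (proportional
fractionation then yields 2.14 Gy per fraction locally).

Sub-seeds are derived per (seed, scenario, patient, organ) through
``numpy.random.SeedSequence`` so cohorts are reproducible and extensible
without reshuffling existing patients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .dose import DoseDistribution, FractionationScheme
from .io import write_dose_distribution, write_tld_sets
from .tld import TLDMeasurementSet

__all__ = [
    "OrganDoseModel",
    "ScenarioSpec",
    "load_default_scenarios",
    "load_scenarios",
    "generate_patient",
    "generate_tld_readings",
    "generate_cohorts",
    "ORGANS",
]

ORGANS = ("heart", "lung_ipsi", "lung_contra", "breast_contra")

#: Organs whose risk is modelled from the TPS-style summed dose distribution.
IN_FIELD_ORGANS = ("heart", "lung_ipsi")
#: Organs whose risk is modelled from TLD mean doses (linear no-threshold).
OUT_OF_FIELD_ORGANS = ("lung_contra", "breast_contra")


@dataclass(frozen=True)
class OrganDoseModel:
    """Calibration of one organ's synthetic dose distribution in a scenario."""

    organ: str
    total_dmean: float  # Gy, cohort mean of the summed physical Dmean
    total_dmean_sd: float  # Gy, patient-to-patient SD
    boost_dmean: float  # Gy, mean-dose share delivered by the boost course
    in_field_fraction: tuple[float, float]  # (mean, sd) of volume near Rx
    penumbra_fraction: tuple[float, float]  # (mean, sd) of 20-80% Rx volume
    oof_mean_gy: float  # exponential tail mean

    def __post_init__(self) -> None:
        if not self.total_dmean > 0:
            raise ValueError(f"{self.organ}: total_dmean must be > 0")
        if self.in_field_fraction[0] + self.penumbra_fraction[0] > 1.0:
            raise ValueError(f"{self.organ}: component fractions exceed 1")
        if self.boost_dmean < 0 or self.boost_dmean >= self.total_dmean:
            raise ValueError(f"{self.organ}: boost_dmean must be in [0, total_dmean)")


@dataclass(frozen=True)
class ScenarioSpec:
    """One treatment scenario: fractionation of its courses plus organ models."""

    name: str
    label: str
    wbi_scheme: FractionationScheme
    boost_scheme: FractionationScheme | None
    boost_kind: str | None  # teletherapy | brachytherapy | None (SiB)
    sib_boost_dose_per_fraction: float | None
    cohort_size: int
    organs: Mapping[str, OrganDoseModel]
    tld_total_gy: Mapping[str, Mapping[str, float]]  # organ -> {small, large}
    tld_outlier_large: frozenset[str]

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise ValueError("cohort_size must be >= 2")


@dataclass(frozen=True)
class StudyConfig:
    """Full study configuration: scenarios plus generator-wide settings."""

    scenarios: dict[str, ScenarioSpec]
    voxels_per_organ: int
    voxel_volume_cm3: float
    dvh_bin_width_gy: float
    tld_readings_per_organ: int
    tld_background_readings: int
    tld_noise_cv: float
    tld_background_gy: float
    tld_outlier_factor: float
    generator_version: int
    raw: dict

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _parse_config(raw: dict) -> StudyConfig:
    sizes = raw["cohort_sizes"]
    scenarios: dict[str, ScenarioSpec] = {}
    for name, sc in raw["scenarios"].items():
        organs = {}
        for organ, om in sc["organs"].items():
            organs[organ] = OrganDoseModel(
                organ=organ,
                total_dmean=float(om["total_dmean"]["mean"]),
                total_dmean_sd=float(om["total_dmean"]["sd"]),
                boost_dmean=float(om["boost_dmean"]),
                in_field_fraction=(
                    float(om["in_field_fraction"]["mean"]),
                    float(om["in_field_fraction"]["sd"]),
                ),
                penumbra_fraction=(
                    float(om["penumbra_fraction"]["mean"]),
                    float(om["penumbra_fraction"]["sd"]),
                ),
                oof_mean_gy=float(om["oof_mean_gy"]),
            )
        boost = sc.get("boost")
        tld_cfg = sc["tld"]
        scenarios[name] = ScenarioSpec(
            name=name,
            label=sc.get("label", name),
            wbi_scheme=FractionationScheme(
                int(sc["wbi"]["n_fractions"]), float(sc["wbi"]["dose_per_fraction"])
            ),
            boost_scheme=(
                FractionationScheme(
                    int(boost["n_fractions"]), float(boost["dose_per_fraction"])
                )
                if boost
                else None
            ),
            boost_kind=boost["kind"] if boost else None,
            sib_boost_dose_per_fraction=(
                float(sc["sib_boost_dose_per_fraction"])
                if sc.get("sib_boost_dose_per_fraction")
                else None
            ),
            cohort_size=int(sizes[name]),
            organs=organs,
            tld_total_gy={
                organ: {k: float(v) for k, v in row.items() if k in ("small", "large")}
                for organ, row in tld_cfg.items()
            },
            tld_outlier_large=frozenset(
                organ for organ, row in tld_cfg.items() if row.get("outlier_large")
            ),
        )
    tld = raw["tld"]
    return StudyConfig(
        scenarios=scenarios,
        voxels_per_organ=int(raw["voxels_per_organ"]),
        voxel_volume_cm3=float(raw["voxel_volume_cm3"]),
        dvh_bin_width_gy=float(raw["dvh_bin_width_gy"]),
        tld_readings_per_organ=int(tld["readings_per_organ"]),
        tld_background_readings=int(tld["background_readings"]),
        tld_noise_cv=float(tld["noise_cv"]),
        tld_background_gy=float(tld["background_gy_per_plan"]),
        tld_outlier_factor=float(tld["outlier_factor"]),
        generator_version=int(raw["generator_version"]),
        raw=raw,
    )


def load_scenarios(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return _parse_config(yaml.safe_load(fh))


def load_default_scenarios() -> StudyConfig:
    text = resources.files("radrisk.data").joinpath("scenarios.yaml").read_text()
    return _parse_config(yaml.safe_load(text))


_SCENARIO_INDEX = {"3dcrt_seq": 0, "3dcrt_brachy": 1, "imrt_brachy": 2, "imrt_sib": 3}


def _rng(seed: int, scenario: str, *stream: int) -> np.random.Generator:
    idx = _SCENARIO_INDEX.get(scenario, 97)
    return np.random.default_rng(np.random.SeedSequence([int(seed), idx, *stream]))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Resampled normal draw truncated below at ``lo``."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    return max(mean, lo + 1e-6)


def _mixture_voxels(
    rng: np.random.Generator,
    n_voxels: int,
    rx_dose: float,
    f_in: float,
    f_pen: float,
    oof_mean: float,
    target_dmean: float,
) -> np.ndarray:
    """Three-component voxel dose mixture rescaled to ``target_dmean``."""
    n_in = int(round(f_in * n_voxels))
    n_pen = int(round(f_pen * n_voxels))
    n_oof = n_voxels - n_in - n_pen
    parts = []
    if n_in:
        parts.append(np.clip(rng.normal(rx_dose, 0.05 * rx_dose, n_in), 0.0, None))
    if n_pen:
        parts.append(rng.uniform(0.2 * rx_dose, 0.8 * rx_dose, n_pen))
    if n_oof:
        parts.append(rng.exponential(oof_mean, n_oof))
    doses = np.concatenate(parts)
    rng.shuffle(doses)
    mean = doses.mean()
    if mean > 0:
        doses *= target_dmean / mean
    return doses


def generate_patient(
    spec: ScenarioSpec,
    seed: int,
    patient_index: int,
    n_voxels: int = 5000,
    voxel_volume: float = 0.125,
) -> dict[str, dict[str, DoseDistribution]]:
    """Per-organ dose distributions of one synthetic patient, per course.

    Returns ``{organ: {"wbi": dist, "boost": dist}}`` (no ``"boost"`` entry
    for the SiB scenario, whose boost is folded into the single course).
    Deterministic in (seed, scenario, patient_index, organ).
    """
    out: dict[str, dict[str, DoseDistribution]] = {}
    for oi, organ in enumerate(ORGANS):
        om = spec.organs[organ]
        rng = _rng(seed, spec.name, patient_index, oi)
        total_t = _truncnorm(rng, om.total_dmean, om.total_dmean_sd, 0.02)
        boost_t = om.boost_dmean * total_t / om.total_dmean
        wbi_t = max(total_t - boost_t, 0.01)
        f_in = max(rng.normal(*om.in_field_fraction), 0.0) if om.in_field_fraction[0] else 0.0
        f_pen = max(rng.normal(*om.penumbra_fraction), 0.0) if om.penumbra_fraction[0] else 0.0
        if f_in + f_pen > 0.9:  # infeasible draw; fall back to configured means
            f_in, f_pen = om.in_field_fraction[0], om.penumbra_fraction[0]
        rx = spec.wbi_scheme.total_dose
        if spec.sib_boost_dose_per_fraction is not None:
            # SiB: single course; in-field voxels carry the boost total dose
            rx = spec.wbi_scheme.n_fractions * spec.sib_boost_dose_per_fraction
        wbi_doses = _mixture_voxels(rng, n_voxels, rx, f_in, f_pen, om.oof_mean_gy, wbi_t)
        courses = {
            "wbi": DoseDistribution(
                organ=organ,
                voxel_doses=wbi_doses,
                voxel_volume=voxel_volume,
                scheme=spec.wbi_scheme,
            )
        }
        if spec.boost_scheme is not None:
            if spec.boost_kind == "brachytherapy":
                # steep source falloff: OAR sees only an exponential tail
                boost_doses = rng.exponential(max(boost_t, 1e-9), n_voxels)
                if boost_t > 0 and boost_doses.mean() > 0:
                    boost_doses *= boost_t / boost_doses.mean()
            else:
                # teletherapy boost: scaled copy of the WBI in-field pattern
                boost_doses = _mixture_voxels(
                    rng,
                    n_voxels,
                    spec.boost_scheme.total_dose,
                    f_in,
                    f_pen,
                    om.oof_mean_gy * 0.2,
                    max(boost_t, 1e-9),
                )
            courses["boost"] = DoseDistribution(
                organ=organ,
                voxel_doses=boost_doses,
                voxel_volume=voxel_volume,
                scheme=spec.boost_scheme,
            )
        out[organ] = courses
    return out


def generate_tld_readings(
    spec: ScenarioSpec,
    breast_size: str,
    seed: int,
    readings_per_organ: int = 5,
    background_readings: int = 3,
    noise_cv: float = 0.10,
    background_gy: float = 0.0002,
    outlier_factor: float = 12.0,
    inject_outlier: bool | None = None,
) -> list[TLDMeasurementSet]:
    """Synthetic per-plan TLD readings for every organ of one phantom setup.

    Readings scatter multiplicatively (lognormal, default CV 10%) around the
    configured per-fraction organ dose plus ambient background; background
    dosimeters scatter around the ambient level alone. For the large-breast
    ipsilateral lung a single "barely in-field" outlier reading is injected
    by default.
    """
    if breast_size not in ("small", "large"):
        raise ValueError(f"breast_size must be 'small' or 'large', got {breast_size!r}")
    n_frac = spec.wbi_scheme.n_fractions
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    sets = []
    for oi, organ in enumerate(ORGANS):
        rng = _rng(seed, spec.name, 10_000 + oi, 0 if breast_size == "small" else 1)
        per_fraction = spec.tld_total_gy[organ][breast_size] / n_frac
        noise = rng.lognormal(-0.5 * sigma**2, sigma, readings_per_organ) if noise_cv > 0 else np.ones(readings_per_organ)
        readings = per_fraction * noise + background_gy
        outlier = (
            inject_outlier
            if inject_outlier is not None
            else (breast_size == "large" and organ in spec.tld_outlier_large)
        )
        if outlier:
            readings[-1] = per_fraction * outlier_factor + background_gy
        bg_noise = rng.lognormal(-0.5 * sigma**2, sigma, background_readings) if noise_cv > 0 else np.ones(background_readings)
        background = background_gy * bg_noise
        sets.append(
            TLDMeasurementSet(
                organ=organ,
                scenario=spec.name,
                breast_size=breast_size,
                readings=readings,
                background=background,
                n_fractions=n_frac,
            )
        )
    return sets


def generate_cohorts(
    config: StudyConfig,
    seed: int,
    out_dir: str | Path,
    cohort_sizes: Mapping[str, int] | None = None,
) -> dict:
    """Generate the full study dataset and write it under ``out_dir``.

    Emits one dose CSV per (scenario, patient, organ, course), one TLD CSV
    and a manifest JSON recording seed, configuration hash and file list.
    Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    sizes = dict(cohort_sizes or {s: sp.cohort_size for s, sp in config.scenarios.items()})
    for name, spec in config.scenarios.items():
        n_patients = sizes[name]
        for p in range(n_patients):
            patient = generate_patient(
                spec, seed, p, config.voxels_per_organ, config.voxel_volume_cm3
            )
            for organ, courses in patient.items():
                for course, dist in courses.items():
                    rel = f"{name}/patient{p:03d}/{organ}_{course}.csv"
                    path = out_dir / rel
                    path.parent.mkdir(parents=True, exist_ok=True)
                    write_dose_distribution(dist, path)
                    files.append(rel)
    tld_sets: list[TLDMeasurementSet] = []
    for name, spec in config.scenarios.items():
        for size in ("small", "large"):
            tld_sets.extend(
                generate_tld_readings(
                    spec,
                    size,
                    seed,
                    config.tld_readings_per_organ,
                    config.tld_background_readings,
                    config.tld_noise_cv,
                    config.tld_background_gy,
                    config.tld_outlier_factor,
                )
            )
    write_tld_sets(tld_sets, out_dir / "tld_readings.csv")
    files.append("tld_readings.csv")
    manifest = {
        "generator_version": config.generator_version,
        "rng": "numpy PCG64 via SeedSequence([seed, scenario, patient, organ])",
        "seed": int(seed),
        "config_sha256": config.config_hash(),
        "cohort_sizes": sizes,
        "n_patients": int(sum(sizes.values())),
        "files": sorted(files),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
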