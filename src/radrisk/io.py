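"""Plain-text readers and writers for dose, DVH and TLD data.

Formats are deliberately simple CSV with ``# key=value`` header comments so
that round-trips are exact (floats serialised with repr precision):

* dose distribution — one dose value (Gy) per row, organ / voxel volume /
  fractionation in the header;
* DVH — ``dose_gy_bin_lower,volume_fraction`` rows plus organ and
  representation-type headers;
* TLD readings — ``scenario,breast_size,organ,tld_id,reading_gy,is_background``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dose import DoseDistribution, DoseVolumeHistogram, FractionationScheme
from .tld import TLDMeasurementSet

__all__ = [
    "write_dose_distribution",
    "read_dose_distribution",
    "write_dvh",
    "read_dvh",
    "write_tld_sets",
    "read_tld_sets",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _read_headers(path: Path) -> dict[str, str]:
    headers: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            headers[key.strip()] = value.strip()
    return headers


def write_dose_distribution(dist: DoseDistribution, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# organ={dist.organ}", f"# voxel_volume_cm3={_fmt(dist.voxel_volume)}"]
    if dist.scheme is None:
        lines.append("# scheme=eqd2_reference")
    else:
        lines.append(f"# n_fractions={dist.scheme.n_fractions}")
        lines.append(f"# dose_per_fraction_gy={_fmt(dist.scheme.dose_per_fraction)}")
    lines.append("dose_gy")
    lines.extend(_fmt(d) for d in dist.voxel_doses)
    path.write_text("\n".join(lines) + "\n")


def read_dose_distribution(path: str | Path) -> DoseDistribution:
    path = Path(path)
    headers = _read_headers(path)
    if headers.get("scheme") == "eqd2_reference":
        scheme = None
    else:
        scheme = FractionationScheme(
            n_fractions=int(headers["n_fractions"]),
            dose_per_fraction=float(headers["dose_per_fraction_gy"]),
        )
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    return DoseDistribution(
        organ=headers["organ"],
        voxel_doses=table["dose_gy"].to_numpy(),
        voxel_volume=float(headers["voxel_volume_cm3"]),
        scheme=scheme,
    )


def write_dvh(dvh: DoseVolumeHistogram, path: str | Path, cumulative: bool = False) -> None:
    path = Path(path)
    lines = [f"# organ={dvh.organ}"]
    if cumulative:
        lines.append("# type=cumulative")
        dose, vol = dvh.cumulative()
        lines.append("dose_gy,volume_fraction")
        lines.extend(f"{_fmt(d)},{_fmt(v)}" for d, v in zip(dose, vol))
    else:
        lines.append("# type=differential")
        lines.append("dose_gy_bin_lower,volume_fraction")
        lines.extend(
            f"{_fmt(lo)},{_fmt(v)}"
            for lo, v in zip(dvh.bin_edges[:-1], dvh.diff_volume)
        )
        lines.append(f"{_fmt(dvh.bin_edges[-1])},{_fmt(0.0)}")  # closing edge row
    path.write_text("\n".join(lines) + "\n")


def read_dvh(path: str | Path) -> DoseVolumeHistogram:
    path = Path(path)
    headers = _read_headers(path)
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    if headers.get("type") == "cumulative":
        dose = table["dose_gy"].to_numpy()
        cum = table["volume_fraction"].to_numpy()
        diff = cum[:-1] - cum[1:]
        return DoseVolumeHistogram(organ=headers["organ"], bin_edges=dose, diff_volume=diff)
    edges = table["dose_gy_bin_lower"].to_numpy()
    vols = table["volume_fraction"].to_numpy()[:-1]
    return DoseVolumeHistogram(organ=headers["organ"], bin_edges=edges, diff_volume=vols)


def write_tld_sets(sets: list[TLDMeasurementSet], path: str | Path) -> None:
    rows = []
    for m in sets:
        for i, r in enumerate(m.readings):
            rows.append((m.scenario, m.breast_size, m.organ, i, _fmt(r), 0, m.n_fractions))
        for i, b in enumerate(m.background):
            rows.append((m.scenario, m.breast_size, m.organ, i, _fmt(b), 1, m.n_fractions))
    frame = pd.DataFrame(
        rows,
        columns=[
            "scenario", "breast_size", "organ", "tld_id",
            "reading_gy", "is_background", "n_fractions",
        ],
    )
    frame.to_csv(path, index=False)


def read_tld_sets(path: str | Path) -> list[TLDMeasurementSet]:
    frame = pd.read_csv(path, float_precision="round_trip")
    sets = []
    for (scenario, size, organ), grp in frame.groupby(
        ["scenario", "breast_size", "organ"], sort=True
    ):
        readings = grp.loc[grp.is_background == 0].sort_values("tld_id")
        background = grp.loc[grp.is_background == 1].sort_values("tld_id")
        sets.append(
            TLDMeasurementSet(
                organ=organ,
                scenario=scenario,
                breast_size=size,
                readings=readings.reading_gy.to_numpy(),
                background=background.reading_gy.to_numpy(),
                n_fractions=int(grp.n_fractions.iloc[0]),
            )
        )
    return sets
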