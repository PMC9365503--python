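"""Versioned registries of literature risk-model parameters.

Parameters ship as YAML data (``data/risk_parameters.yaml``) preloaded with
the Schneider lung/breast rows, the two LKB lung pneumonitis endpoints and
the Darby cardiac slope; users can load an extended registry from their own
file with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .darby import DARBY_SLOPE_PER_GY
from .lkb import LKBParams
from .schneider import SchneiderParams

__all__ = ["RiskParameterSet", "load_default_parameters", "load_parameters"]


@dataclass(frozen=True)
class RiskParameterSet:
    """Bundle of Schneider, LKB and Darby parameters keyed by organ/endpoint."""

    alpha_beta: float
    schneider: dict[str, SchneiderParams]
    lkb: dict[tuple[str, str], LKBParams]
    darby_slope: float = DARBY_SLOPE_PER_GY

    def schneider_for(self, organ: str) -> SchneiderParams:
        try:
            return self.schneider[organ]
        except KeyError:
            raise KeyError(
                f"no Schneider parameters for organ {organ!r}; "
                f"known: {sorted(self.schneider)}"
            ) from None

    def lkb_for(self, organ: str, endpoint: str) -> LKBParams:
        try:
            return self.lkb[(organ, endpoint)]
        except KeyError:
            raise KeyError(
                f"no LKB parameters for {(organ, endpoint)!r}; "
                f"known: {sorted(self.lkb)}"
            ) from None

    def lkb_endpoints(self, organ: str) -> list[str]:
        return sorted(ep for (org, ep) in self.lkb if org == organ)


def _parse(raw: dict) -> RiskParameterSet:
    ab = float(raw.get("alpha_beta", 3.0))
    schneider = {
        organ: SchneiderParams(
            organ=organ,
            delta=float(row["delta"]),
            gamma_e=float(row["gamma_e"]),
            gamma_a=float(row["gamma_a"]),
            alpha_lq=float(row["alpha"]),
            repop=float(row["repop"]),
            ab=ab,
        )
        for organ, row in raw.get("schneider", {}).items()
    }
    lkb = {
        (organ, endpoint): LKBParams(
            endpoint=endpoint,
            n_volume=float(row["n"]),
            m_slope=float(row["m"]),
            d50=float(row["d50"]),
        )
        for organ, endpoints in raw.get("lkb", {}).items()
        for endpoint, row in endpoints.items()
    }
    darby = float(raw.get("darby", {}).get("err_per_gy", DARBY_SLOPE_PER_GY))
    return RiskParameterSet(alpha_beta=ab, schneider=schneider, lkb=lkb, darby_slope=darby)


def load_parameters(path: str | Path) -> RiskParameterSet:
    """Load a risk-parameter registry from a YAML file."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def load_default_parameters() -> RiskParameterSet:
    """The registry shipped with the package."""
    text = resources.files("radrisk.data").joinpath("risk_parameters.yaml").read_text()
    return _parse(yaml.safe_load(text))
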