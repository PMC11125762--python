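"""Hazard quotients and lifetime cancer risk from exposure concentrations.

Non-cancer screening uses the hazard quotient HQ = C / RfC, where C is the
long-term exposure concentration (µg/m³) and RfC the inhalation reference
concentration below which adverse effects are not expected. Lifetime cancer
risk amortizes exposure over a lifetime:

    CR = C · UR · (ED / AT)

with UR the inhalation unit risk ((µg/m³)⁻¹), ED the exposure duration and
AT the averaging time (lifetime), both in years (defaults 40 and 78). No
exposure-frequency or inhalation-rate term is applied: concentrations are
assumed already expressed as long-term exposure concentrations. Totals sum
over compounds, so an aggregate HQ above 1 flags potential non-cancer
concern for the mixture.

Toxicity parameters (RfC, unit risk) are user-supplied input tables —
typically transcribed from the EPA CompTox/IRIS databases, whose values are
version-dependent — never bundled with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd


@dataclass(frozen=True)
class ToxParams:
    """Inhalation toxicity parameters for one compound."""

    compound: str
    rfc_ug_m3: float | None = None
    unit_risk_per_ug_m3: float = 0.0

    def __post_init__(self) -> None:
        if self.rfc_ug_m3 is not None and self.rfc_ug_m3 <= 0:
            raise ValueError(f"{self.compound}: RfC must be positive if given")
        if self.unit_risk_per_ug_m3 < 0:
            raise ValueError(f"{self.compound}: unit risk must be >= 0")


@dataclass(frozen=True)
class ExposureParams:
    """Exposure duration and averaging lifetime, in years."""

    exposure_duration_yr: float = 40.0
    lifetime_yr: float = 78.0

    def __post_init__(self) -> None:
        if not 0 < self.exposure_duration_yr <= self.lifetime_yr:
            raise ValueError(
                "need 0 < exposure_duration_yr <= lifetime_yr, got "
                f"{self.exposure_duration_yr} / {self.lifetime_yr}"
            )


@dataclass(frozen=True)
class RiskResult:
    """Per-compound and aggregate HQ and lifetime cancer risk."""

    per_compound_hq: dict[str, float]
    hq_total: float
    per_compound_cr: dict[str, float]
    cr_total: float
    concentrations_ug_m3: dict[str, float] = field(default_factory=dict)
    exposure: ExposureParams = field(default_factory=ExposureParams)

    def as_dict(self) -> dict:
        return {
            "per_compound_hq": dict(self.per_compound_hq),
            "hq_total": self.hq_total,
            "per_compound_cr": dict(self.per_compound_cr),
            "cr_total": self.cr_total,
            "concentrations_ug_m3": dict(self.concentrations_ug_m3),
            "exposure_duration_yr": self.exposure.exposure_duration_yr,
            "lifetime_yr": self.exposure.lifetime_yr,
        }


def hazard_quotient(c_ug_m3: float, tox: ToxParams) -> float:
    """HQ = concentration / reference concentration."""
    if c_ug_m3 < 0:
        raise ValueError("concentration must be non-negative")
    if tox.rfc_ug_m3 is None:
        raise ValueError(f"no RfC available for {tox.compound}")
    return c_ug_m3 / tox.rfc_ug_m3


def cancer_risk(
    c_ug_m3: float, tox: ToxParams, exp: ExposureParams | None = None
) -> float:
    """CR = concentration · unit risk · (exposure duration / lifetime)."""
    if c_ug_m3 < 0:
        raise ValueError("concentration must be non-negative")
    if exp is None:
        exp = ExposureParams()
    return (
        c_ug_m3
        * tox.unit_risk_per_ug_m3
        * (exp.exposure_duration_yr / exp.lifetime_yr)
    )


def aggregate_risk(
    concentrations: Mapping[str, float],
    tox_table: Sequence[ToxParams] | Mapping[str, ToxParams],
    exp: ExposureParams | None = None,
) -> RiskResult:
    """HQ and CR per compound plus totals over the mixture.

    Every compound in ``concentrations`` must have a toxicity entry; RfC is
    required (HQ is always computed), unit risk may be zero for
    non-carcinogens.
    """
    if exp is None:
        exp = ExposureParams()
    if not isinstance(tox_table, Mapping):
        tox_table = {t.compound: t for t in tox_table}
    missing = sorted(set(concentrations) - set(tox_table))
    if missing:
        raise ValueError(f"no toxicity parameters for: {missing}")
    hq = {c: hazard_quotient(v, tox_table[c]) for c, v in concentrations.items()}
    cr = {c: cancer_risk(v, tox_table[c], exp) for c, v in concentrations.items()}
    return RiskResult(
        per_compound_hq=hq,
        hq_total=sum(hq.values()),
        per_compound_cr=cr,
        cr_total=sum(cr.values()),
        concentrations_ug_m3=dict(concentrations),
        exposure=exp,
    )


def read_tox_table(path: Union[str, Path]) -> dict[str, ToxParams]:
    """Read a toxicity table: columns compound, rfc_ug_m3, unit_risk_per_ug_m3.

    An empty RfC cell means "no reference concentration available"; the unit
    risk column defaults to 0 (non-carcinogen) when empty.
    """
    df = pd.read_csv(path)
    required = {"compound", "rfc_ug_m3", "unit_risk_per_ug_m3"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    table = {}
    for _, row in df.iterrows():
        rfc = row["rfc_ug_m3"]
        ur = row["unit_risk_per_ug_m3"]
        table[str(row["compound"])] = ToxParams(
            compound=str(row["compound"]),
            rfc_ug_m3=None if pd.isna(rfc) else float(rfc),
            unit_risk_per_ug_m3=0.0 if pd.isna(ur) else float(ur),
        )
    return table


def read_concentrations(path: Union[str, Path]) -> dict[str, float]:
    """Read a concentration table: columns compound, concentration_ug_m3."""
    df = pd.read_csv(path)
    required = {"compound", "concentration_ug_m3"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return {
        str(r["compound"]): float(r["concentration_ug_m3"])
        for _, r in df.iterrows()
    }
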