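"""Fish-consumption risk battery.

Implements the standard dietary risk chain for trace elements in fish
muscle:

* BCF — bioconcentration factor, tissue concentration over dissolved
  water concentration (L/kg),
* MPI — metal pollution index, the geometric mean of all element
  concentrations in a tissue sample; MPI > 1 flags potential risk,
* EDI — estimated daily intake, C·IR/BW (mg/kg-bw/day), optionally the
  full C·IR·EF·ED/(BW·AT) form,
* THQ — target hazard quotient EDI/RfD, HI — the sum of THQs,
* CR — carcinogenic risk EDI·CSF with the conventional bands
  (<1e-6 negligible, [1e-6, 1e-4) acceptable, ≥1e-4 significant),
  TCR — the sum over tracked carcinogens,
* regulatory screening of mean tissue levels against per-authority
  maximum permissible limits (MPLs).

All of them are exposed both as plain functions and through the
:class:`DietaryRiskAssessor` estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import (
    CARCINOGENS,
    ConcentrationTable,
    ExposureScenario,
    RiskReport,
    ToxParamRegistry,
)
from .units import convert_units

CR_NEGLIGIBLE = 1e-6
CR_SIGNIFICANT = 1e-4


def bcf(c_fish: float, c_water_ugL: float) -> float:
    """Bioconcentration factor (L/kg) from fish mg/kg-ww and water µg/L.

    The water concentration is converted to mg/L so the ratio carries
    units of L/kg. Zero fish concentration gives 0; a non-positive water
    concentration makes the ratio undefined.
    """
    if c_water_ugL <= 0:
        raise ValueError(
            f"BCF undefined: water concentration must be > 0, got {c_water_ugL}"
        )
    return c_fish / convert_units(c_water_ugL, "µg/L", "mg/L")


def mpi(concentrations, policy: str = "strict") -> float:
    """Metal pollution index: geometric mean of the concentrations.

    Scale-equivariant (mpi(k·C) = k·mpi(C)) and bounded by the min and
    max concentration. The geometric mean is undefined at 0, so zeros
    are an error under ``policy="strict"``; ``policy="drop"`` removes
    them with a warning.
    """
    if isinstance(concentrations, dict):
        values = pd.Series(concentrations, dtype=float)
    else:
        values = pd.Series(np.asarray(concentrations, dtype=float))
    values = values.dropna()
    if len(values) == 0:
        raise ValueError("MPI needs at least one concentration")
    zeros = values.index[values <= 0].tolist()
    if zeros:
        if policy == "strict":
            raise ValueError(
                f"MPI undefined: non-positive concentration for {zeros}"
            )
        if policy == "drop":
            warnings.warn(f"MPI: dropping non-positive entries {zeros}")
            values = values[values > 0]
            if len(values) == 0:
                raise ValueError("MPI: all concentrations dropped")
        else:
            raise ValueError(f"MPI policy must be strict|drop, got {policy!r}")
    return float(np.exp(np.mean(np.log(values.to_numpy()))))


def edi(c_fish: float, scenario: ExposureScenario) -> float:
    """Estimated daily intake, mg per kg body weight per day."""
    return (
        c_fish * scenario.ingestion_rate / scenario.body_weight
        * scenario.chronic_factor
    )


def thq(edi_value: float, rfd: float) -> float:
    """Target hazard quotient EDI/RfD; > 1 flags possible
    non-carcinogenic effects."""
    if rfd <= 0:
        raise ValueError(f"RfD must be > 0, got {rfd}")
    return edi_value / rfd


def hi(thq_values) -> float:
    """Hazard index: arithmetic sum of THQs over elements."""
    arr = np.asarray(list(thq_values), dtype=float)
    if arr.size == 0:
        raise ValueError("HI needs at least one THQ value")
    return float(arr.sum())


def cr(edi_value: float, csf: float) -> float:
    """Carcinogenic risk EDI·CSF (dimensionless lifetime probability)."""
    if csf <= 0:
        raise ValueError(f"CSF must be > 0, got {csf}")
    return edi_value * csf


def cr_band(risk: float) -> str:
    """Band a carcinogenic risk: half-open bands [1e-6, 1e-4)."""
    if risk < CR_NEGLIGIBLE:
        return "negligible"
    if risk < CR_SIGNIFICANT:
        return "acceptable"
    return "significant"


def tcr(cr_values) -> float:
    """Total carcinogenic risk: sum of per-element risks (0 if empty)."""
    arr = np.asarray(list(cr_values), dtype=float)
    return float(arr.sum()) if arr.size else 0.0


def screen_mpl(
    means: pd.Series | dict,
    registry: ToxParamRegistry,
    authority: str,
) -> pd.DataFrame:
    """Screen mean tissue concentrations against one authority's MPLs.

    Returns a frame indexed by element with the limit, the mean/limit
    ratio and an ``exceeds`` flag; elements the authority does not limit
    get status ``no limit``.
    """
    if authority not in registry.mpl_authorities:
        raise KeyError(
            f"unknown authority {authority!r}; available: "
            f"{sorted(registry.mpl_authorities)}"
        )
    means = pd.Series(means, dtype=float)
    rows = []
    for el, mean in means.items():
        limit = registry.mpl(el, authority)
        if limit is None:
            rows.append({"element": el, "mean": mean, "limit": np.nan,
                         "ratio": np.nan, "exceeds": False, "status": "no limit"})
        else:
            ratio = mean / limit
            rows.append({"element": el, "mean": mean, "limit": limit,
                         "ratio": ratio, "exceeds": bool(ratio > 1),
                         "status": "exceeds" if ratio > 1 else "compliant"})
    return pd.DataFrame(rows).set_index("element")


class DietaryRiskAssessor(BaseEstimator, TransformerMixin):
    """Estimator computing the full dietary risk battery per station.

    Parameters
    ----------
    registry : ToxParamRegistry, optional
        Toxicological constants; the packaged editable defaults if None.
    scenario : ExposureScenario, optional
        Intake assumptions; adult defaults (55 g/day, 70 kg) if None.
    carcinogens : sequence of str
        Elements entering CR/TCR (must have a CSF in the registry).
    mpi_policy : {"strict", "drop"}
        Zero handling for the geometric mean.

    Attributes
    ----------
    report_ : RiskReport
        Per-element BCF/EDI/THQ/CR frames and per-station MPI/HI/TCR
        with classification flags, populated by :meth:`fit`.
    """

    def __init__(self, registry=None, scenario=None,
                 carcinogens=CARCINOGENS, mpi_policy="strict"):
        self.registry = registry
        self.scenario = scenario
        self.carcinogens = carcinogens
        self.mpi_policy = mpi_policy

    def fit(self, fish: ConcentrationTable, water: ConcentrationTable | None = None):
        registry = self.registry or ToxParamRegistry.default()
        scenario = self.scenario or ExposureScenario()
        values = fish.values
        stations = values.index

        report = RiskReport(meta={
            "scenario": {
                "ingestion_rate": scenario.ingestion_rate,
                "body_weight": scenario.body_weight,
                "chronic_factor": scenario.chronic_factor,
            },
            "mpi_policy": self.mpi_policy,
        })

        if water is not None:
            common = [e for e in values.columns if e in water.values.columns]
            wsub = water.values.reindex(index=stations)[common]
            if (wsub <= 0).any().any():
                bad = wsub.columns[(wsub <= 0).any()].tolist()
                raise ValueError(
                    f"BCF undefined: non-positive water concentrations for {bad}"
                )
            report.per_element["bcf"] = values[common] / (wsub * 1e-3)

        report.per_element["edi"] = (
            values * scenario.ingestion_rate / scenario.body_weight
            * scenario.chronic_factor
        )

        rfd_missing = [e for e in values.columns
                       if np.isnan(registry._value("rfd", e))]
        if rfd_missing:
            raise KeyError(f"no oral reference dose (rfd) for {rfd_missing}")
        rfds = pd.Series({e: registry.rfd(e) for e in values.columns})
        report.per_element["thq"] = report.per_element["edi"] / rfds

        tracked = [e for e in self.carcinogens if e in values.columns]
        with_csf, without_csf = [], []
        for e in tracked:
            (with_csf if registry.csf(e) is not None else without_csf).append(e)
        if without_csf:
            warnings.warn(
                f"carcinogens without a cancer slope factor excluded from "
                f"CR/TCR: {without_csf}"
            )
        csfs = pd.Series({e: registry.csf(e) for e in with_csf}, dtype=float)
        report.per_element["cr"] = report.per_element["edi"][with_csf] * csfs

        per_station = pd.DataFrame(index=stations)
        per_station["mpi"] = [
            mpi(values.loc[st], policy=self.mpi_policy) for st in stations
        ]
        per_station["hi"] = report.per_element["thq"].sum(axis=1)
        per_station["tcr"] = report.per_element["cr"].sum(axis=1)
        per_station["mpi_flag"] = per_station["mpi"] > 1
        per_station["hi_flag"] = per_station["hi"] > 1
        per_station["tcr_band"] = per_station["tcr"].map(cr_band)
        report.per_station = per_station
        report.meta["cr_excluded"] = without_csf
        report.validate()

        self.report_ = report
        return self

    def transform(self, fish=None, water=None) -> pd.DataFrame:
        """Per-station scalar indices (MPI, HI, TCR) of the fitted data."""
        if not hasattr(self, "report_"):
            self.fit(fish, water)
        return self.report_.per_station.copy()

    def assess(self, fish: ConcentrationTable,
               water: ConcentrationTable | None = None) -> RiskReport:
        """One-call convenience: fit and return the populated report."""
        return self.fit(fish, water).report_


def assess_dietary_risk(fish, water=None, registry=None, scenario=None,
                        **kwargs) -> RiskReport:
    """Functional wrapper over :class:`DietaryRiskAssessor`."""
    return DietaryRiskAssessor(
        registry=registry, scenario=scenario, **kwargs
    ).assess(fish, water)
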