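"""Water-side pollution indices: WQI, HPI, HEI.

* WQI — weighted-arithmetic water quality index. Sub-index
  qᵢ = 100·Cᵢ/Sᵢ against the permissible standard Sᵢ; weights
  wᵢ ∝ 1/Sᵢ normalized to sum 1; WQI = Σ wᵢ qᵢ. Classes:
  <50 excellent, 50–100 good, 100–200 poor, 200–300 very poor,
  ≥300 unfit for drinking.
* HPI — heavy metal pollution index. Rating Qᵢ = 100·|Cᵢ−Iᵢ|/(Sᵢ−Iᵢ)
  with ideal value Iᵢ (default 0), weights Wᵢ ∝ 1/Sᵢ;
  HPI = ΣWᵢQᵢ/ΣWᵢ, critical value 100. With Iᵢ = 0 HPI coincides with
  WQI on identical inputs.
* HEI — heavy metal evaluation index, Σ Cᵢ/MACᵢ against maximum
  admissible concentrations. Classes: <10 low, 10–20 medium, >20 high.

The weighted-arithmetic WQI variant is one of several published ones;
the variant name is recorded in the output metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import ConcentrationTable, ToxParamRegistry

WQI_VARIANT = "weighted-arithmetic (w_i = k/S_i)"

WQI_BANDS = ((50, "excellent"), (100, "good"), (200, "poor"),
             (300, "very poor"), (np.inf, "unfit"))
HEI_BANDS = ((10, "low"), (20, "medium"), (np.inf, "high"))


def classify_wqi(value: float) -> str:
    for upper, label in WQI_BANDS:
        if value < upper:
            return label
    return WQI_BANDS[-1][1]


def classify_hpi(value: float) -> str:
    return "low pollution" if value < 100 else "high pollution"


def classify_hei(value: float) -> str:
    if value < 10:
        return "low"
    if value <= 20:
        return "medium"
    return "high"


def _aligned(c, std, what: str) -> tuple[pd.Series, pd.Series]:
    c = pd.Series(c, dtype=float)
    std = pd.Series(std, dtype=float)
    missing = [e for e in c.index if e not in std.index or np.isnan(std.get(e))]
    if missing:
        warnings.warn(f"{what}: elements without a standard excluded: {missing}")
    keep = [e for e in c.index if e not in missing]
    if not keep:
        raise ValueError(f"{what}: no element has a defined standard")
    c, std = c[keep], std[keep]
    if (std <= 0).any():
        raise ValueError(f"{what}: standards must be > 0")
    return c, std


def wqi(c, std, *, detailed: bool = False):
    """Weighted-arithmetic WQI from µg/L concentrations and standards.

    Returns ``(value, class)``; with ``detailed=True`` also the
    per-element sub-indices and normalized weights.
    """
    c, std = _aligned(c, std, "WQI")
    q = 100.0 * c / std
    w = (1.0 / std) / (1.0 / std).sum()
    value = float((w * q).sum())
    if detailed:
        return value, classify_wqi(value), pd.DataFrame({"q": q, "w": w})
    return value, classify_wqi(value)


def hpi(c, std, ideal=0.0, *, detailed: bool = False):
    """Heavy metal pollution index with ideal values Iᵢ (default 0)."""
    c, std = _aligned(c, std, "HPI")
    ideal = pd.Series(ideal, index=c.index, dtype=float) if np.isscalar(ideal) \
        else pd.Series(ideal, dtype=float).reindex(c.index).fillna(0.0)
    if (std == ideal).any():
        bad = c.index[(std == ideal)].tolist()
        raise ValueError(f"HPI undefined where S_i equals I_i: {bad}")
    Q = 100.0 * (c - ideal).abs() / (std - ideal)
    W = 1.0 / std
    value = float((W * Q).sum() / W.sum())
    if detailed:
        return value, classify_hpi(value), pd.DataFrame({"Q": Q, "W": W / W.sum()})
    return value, classify_hpi(value)


def hei(c, mac):
    """Heavy metal evaluation index Σ Cᵢ/MACᵢ."""
    c, mac = _aligned(c, mac, "HEI")
    value = float((c / mac).sum())
    return value, classify_hei(value)


class WaterQualityIndexer(BaseEstimator, TransformerMixin):
    """Estimator computing WQI/HPI/HEI per station from a water table.

    Standards Sᵢ and MACᵢ come from the registry (packaged editable
    defaults if None). Fitted attribute ``result_`` is a per-station
    frame with each index value and class.
    """

    def __init__(self, registry=None, ideal=0.0):
        self.registry = registry
        self.ideal = ideal

    def fit(self, water: ConcentrationTable, y=None):
        registry = self.registry or ToxParamRegistry.default()
        std = pd.Series({e: registry.std_water(e) for e in water.elements},
                        dtype=float)
        mac = pd.Series({e: registry.mac_water(e) for e in water.elements},
                        dtype=float)
        rows = []
        details = {}
        for st in water.stations:
            c = water.values.loc[st]
            w_val, w_cls, w_det = wqi(c, std, detailed=True)
            h_val, h_cls, h_det = hpi(c, std, ideal=self.ideal, detailed=True)
            e_val, e_cls = hei(c, mac)
            rows.append({"station": st,
                         "wqi": w_val, "wqi_class": w_cls,
                         "hpi": h_val, "hpi_class": h_cls,
                         "hei": e_val, "hei_class": e_cls})
            details[st] = {"wqi": w_det, "hpi": h_det}
        self.result_ = pd.DataFrame(rows).set_index("station")
        self.details_ = details
        self.meta_ = {"wqi_variant": WQI_VARIANT, "ideal": self.ideal}
        return self

    def transform(self, water=None) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            self.fit(water)
        return self.result_.copy()


def assess_water_quality(water, registry=None, ideal=0.0) -> pd.DataFrame:
    """Functional wrapper over :class:`WaterQualityIndexer`."""
    return WaterQualityIndexer(registry=registry, ideal=ideal).fit(water).result_


def radar_summary(result: pd.DataFrame) -> pd.DataFrame:
    """Long-format station,index,value,class table for radar/bar plots.

    Pure projection of the per-station result frame; stations keep
    input order, indices appear in the fixed order wqi, hpi, hei.
    """
    rows = []
    for st in result.index:
        for name in ("wqi", "hpi", "hei"):
            if name in result.columns:
                rows.append({
                    "station": st, "index": name,
                    "value": result.loc[st, name],
                    "class": result.loc[st, f"{name}_class"],
                })
    return pd.DataFrame(rows, columns=["station", "index", "value", "class"])
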