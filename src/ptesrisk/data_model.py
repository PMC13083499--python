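"""Core domain containers and delimited-file I/O.

The pipeline's canonical in-memory object is :class:`ConcentrationTable`:
a station × element matrix of non-negative concentrations with a medium
tag (``fish`` in mg/kg wet weight, ``water`` in µg/L), optional planar
station coordinates, and a censoring mask for below-detection entries.

Toxicological constants (oral reference doses, cancer slope factors,
regulatory tissue limits per authority, water standards) live in
:class:`ToxParamRegistry`, shipped as an editable CSV so studies can
substitute their own parameter sets without touching code.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .units import canonical_unit

NONDETECT_POLICIES = ("zero", "lod_half", "drop")

# element panel of the study: 13 quantified analytes + boron
DEFAULT_PANEL = (
    "Fe", "Zn", "Al", "Cu", "Mn", "As", "Se",
    "Cr", "Ni", "Pb", "Hg", "Co", "Cd", "B",
)

# carcinogen panel, ordered by mean carcinogenic risk in farmed trout
CARCINOGENS = ("As", "Cr", "Ni", "Cd", "Pb")


@dataclass(frozen=True)
class ElementRecord:
    """One analyte in the panel."""

    symbol: str
    name: str = ""
    is_carcinogen_tracked: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("element symbol must be non-empty")


def default_elements() -> list[ElementRecord]:
    return [
        ElementRecord(sym, is_carcinogen_tracked=sym in CARCINOGENS)
        for sym in DEFAULT_PANEL
    ]


@dataclass
class ConcentrationTable:
    """Station × element concentration matrix for one medium.

    Attributes
    ----------
    medium : {"fish", "water"}
    values : pandas.DataFrame
        Index = station ids (input order preserved, never sorted),
        columns = element symbols, entries non-negative.
    units : str
        ``mg/kg`` for fish (wet weight), ``µg/L`` for water.
    coordinates : pandas.DataFrame or None
        Planar (x, y) per station, same index as ``values``.
    censored : pandas.DataFrame
        Boolean mask marking entries that were below detection and
        substituted per the nondetect policy.
    """

    medium: str
    values: pd.DataFrame
    units: str = ""
    coordinates: pd.DataFrame | None = None
    censored: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    detection_limit: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.medium not in ("fish", "water"):
            raise ValueError(f"medium must be fish|water, got {self.medium!r}")
        if not self.units:
            self.units = canonical_unit(self.medium)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate station ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if np.isfinite(vals).all() and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative concentration at station {self.values.index[r]!r}, "
                f"element {self.values.columns[c]!r}"
            )
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.coordinates is not None:
            if not self.coordinates.index.equals(self.values.index):
                raise ValueError("coordinates must cover exactly the stations")
            if list(self.coordinates.columns) != ["x", "y"]:
                self.coordinates = self.coordinates[["x", "y"]]

    @property
    def stations(self) -> list[str]:
        return list(self.values.index)

    @property
    def elements(self) -> list[str]:
        return list(self.values.columns)

    def element_means(self) -> pd.Series:
        """Arithmetic mean concentration per element over stations."""
        return self.values.mean(axis=0)

    def subset(self, elements: Iterable[str]) -> "ConcentrationTable":
        cols = [e for e in elements if e in self.values.columns]
        return ConcentrationTable(
            medium=self.medium,
            values=self.values[cols].copy(),
            units=self.units,
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
            censored=self.censored[cols].copy(),
        )


_LOD_RE = re.compile(r"^\s*<\s*(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*$")


def read_concentration_table(
    path: str | Path,
    medium: str,
    *,
    nondetect_policy: str = "lod_half",
    sep: str = ",",
    allowed_elements: Iterable[str] | None = None,
    allow_extra_columns: bool = False,
) -> ConcentrationTable:
    """Read a wide-format station × element table.

    Expected header: ``station[,x,y],<El1>,<El2>,...``. Below-detection
    entries encoded ``<LOD`` (e.g. ``<0.01``) or left blank are replaced
    per ``nondetect_policy``:

    * ``lod_half`` — LOD/2 (blank cells without an LOD become 0), flagged
    * ``zero`` — 0, flagged
    * ``drop`` — NaN, flagged (rows are kept; downstream ops use
      pairwise deletion)
    """
    if nondetect_policy not in NONDETECT_POLICIES:
        raise ValueError(
            f"nondetect_policy must be one of {NONDETECT_POLICIES}, "
            f"got {nondetect_policy!r}"
        )
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "station" not in raw.columns:
        raise ValueError(f"{path}: missing required 'station' column")
    raw = raw.set_index("station")
    coord_cols = [c for c in ("x", "y") if c in raw.columns]
    coords = None
    if coord_cols:
        if coord_cols != ["x", "y"]:
            raise ValueError(f"{path}: coordinates need both x and y columns")
        coords = raw[["x", "y"]].astype(float)
    element_cols = [c for c in raw.columns if c not in ("x", "y")]
    if allowed_elements is not None:
        unknown = [c for c in element_cols if c not in set(allowed_elements)]
        if unknown and not allow_extra_columns:
            raise ValueError(f"{path}: unknown element columns {unknown}")
        if unknown:
            element_cols = [c for c in element_cols if c not in unknown]

    values = pd.DataFrame(index=raw.index, columns=element_cols, dtype=float)
    censored = pd.DataFrame(False, index=raw.index, columns=element_cols)
    for col in element_cols:
        for st, cell in raw[col].items():
            cell = cell.strip()
            m = _LOD_RE.match(cell)
            if m or cell == "":
                lod = float(m.group(1)) if m else 0.0
                if nondetect_policy == "lod_half":
                    values.loc[st, col] = lod / 2.0
                elif nondetect_policy == "zero":
                    values.loc[st, col] = 0.0
                else:  # drop
                    values.loc[st, col] = np.nan
                censored.loc[st, col] = True
            else:
                v = float(cell)
                if v < 0:
                    raise ValueError(
                        f"{path}: negative value {v} at station {st!r}, "
                        f"element {col!r}"
                    )
                values.loc[st, col] = v
    return ConcentrationTable(
        medium=medium, values=values, coordinates=coords, censored=censored
    )


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write a table back to wide CSV (inverse of the reader for detects)."""
    out = table.values.copy()
    if table.coordinates is not None:
        out = pd.concat([table.coordinates, out], axis=1)
    out.index.name = "station"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# toxicological parameter registry


@dataclass
class ToxParamRegistry:
    """Per-element toxicological constants and regulatory limits.

    ``rfd`` oral reference dose (mg/kg-bw/day), ``csf`` cancer slope
    factor ((mg/kg-bw/day)⁻¹), ``std_water`` permissible standard Sᵢ and
    ``mac_water`` maximum admissible concentration MACᵢ (both µg/L), and
    one tissue limit column per authority (mg/kg). The packaged defaults
    are editable, literature-style values — replace the CSV to match a
    specific study's parameter set.
    """

    table: pd.DataFrame
    mpl_authorities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.table = self.table.set_index("element") if "element" in self.table else self.table
        mpl_cols = [c for c in self.table.columns if c.startswith("mpl_")]
        self.mpl_authorities = tuple(c[len("mpl_"):] for c in mpl_cols)
        for col, cond in (("rfd", "positive"), ("csf", "positive"),
                          ("std_water_ugL", "positive"), ("mac_water_ugL", "positive")):
            if col in self.table:
                bad = self.table[col].dropna() <= 0
                if bad.any():
                    raise ValueError(
                        f"{col} must be > 0 where present; offending elements: "
                        f"{self.table.index[self.table[col].fillna(1) <= 0].tolist()}"
                    )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ToxParamRegistry":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "ToxParamRegistry":
        with resources.files("ptesrisk.data").joinpath("tox_params.csv").open() as fh:
            return cls(pd.read_csv(fh))

    def _column(self, name: str) -> pd.Series:
        if name not in self.table:
            raise KeyError(f"registry has no column {name!r}")
        return self.table[name]

    def rfd(self, element: str) -> float:
        v = self._value("rfd", element)
        if np.isnan(v):
            raise KeyError(f"no oral reference dose (rfd) for element {element!r}")
        return v

    def csf(self, element: str) -> float | None:
        v = self._value("csf", element)
        return None if np.isnan(v) else v

    def std_water(self, element: str) -> float | None:
        v = self._value("std_water_ugL", element)
        return None if np.isnan(v) else v

    def mac_water(self, element: str) -> float | None:
        v = self._value("mac_water_ugL", element)
        return None if np.isnan(v) else v

    def mpl(self, element: str, authority: str) -> float | None:
        col = f"mpl_{authority}"
        if col not in self.table:
            raise KeyError(
                f"unknown authority {authority!r}; available: "
                f"{sorted(self.mpl_authorities)}"
            )
        return None if np.isnan(self._value(col, element)) else self._value(col, element)

    def _value(self, column: str, element: str) -> float:
        if element not in self.table.index:
            return float("nan")
        return float(self._column(column).get(element, float("nan")))


@dataclass(frozen=True)
class ExposureScenario:
    """Fish-consumption exposure assumptions for the intake chain.

    The default chain is the two-parameter form EDI = C·IR/BW. When
    exposure frequency (days/yr), duration (yr) and averaging time (days)
    are all supplied, the full form C·IR·EF·ED/(BW·AT) is used; with
    EF·ED = AT/365·365 the two coincide.
    """

    ingestion_rate: float = 0.055  # kg fish/day, adult consumer
    body_weight: float = 70.0      # kg
    exposure_frequency: float | None = None  # days/year
    exposure_duration: float | None = None   # years
    averaging_time: float | None = None      # days

    def __post_init__(self) -> None:
        if self.ingestion_rate <= 0:
            raise ValueError("ingestion_rate must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        extras = (self.exposure_frequency, self.exposure_duration, self.averaging_time)
        supplied = [e is not None for e in extras]
        if any(supplied) and not all(supplied):
            raise ValueError(
                "exposure_frequency, exposure_duration and averaging_time "
                "must be supplied together"
            )

    @property
    def chronic_factor(self) -> float:
        """EF·ED/AT multiplier; 1.0 in the two-parameter form."""
        if self.exposure_frequency is None:
            return 1.0
        return (
            self.exposure_frequency * self.exposure_duration / self.averaging_time
        )


# ---------------------------------------------------------------------------
# risk report container


@dataclass
class RiskReport:
    """Per-station / per-element risk index values with classifications.

    ``per_element`` frames are station × element (bcf, edi, thq, cr);
    ``per_station`` holds the scalar indices (mpi, hi, tcr) and flags.
    """

    per_element: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_station: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, frame in self.per_element.items():
            vals = frame.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"negative entries in {name}")
        if "hi" in self.per_station and "thq" in self.per_element:
            resid = np.abs(
                self.per_station["hi"] - self.per_element["thq"].sum(axis=1)
            )
            if resid.max() > 1e-12:
                raise ValueError("hi is not the sum of thq components")
        if "tcr" in self.per_station and "cr" in self.per_element:
            resid = np.abs(
                self.per_station["tcr"] - self.per_element["cr"].sum(axis=1)
            )
            if resid.max() > 1e-12:
                raise ValueError("tcr is not the sum of cr components")


def write_report(report: RiskReport, path: str | Path, fmt: str = "csv") -> None:
    """Serialize a risk report at full precision.

    ``csv`` writes a long table ``station,index,element,value``; scalar
    indices use an empty element field. ``json`` writes a nested document
    with the same content plus metadata.
    """
    path = Path(path)
    if fmt == "csv":
        rows = []
        for name, frame in report.per_element.items():
            long = frame.stack().rename("value").reset_index()
            long.columns = ["station", "element", "value"]
            long.insert(1, "index", name)
            rows.append(long)
        for col in report.per_station.columns:
            s = report.per_station[col].rename("value").reset_index()
            s.columns = ["station", "value"]
            s.insert(1, "index", col)
            s.insert(2, "element", "")
            rows.append(s)
        out = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["station", "index", "element", "value"])
        )
        out.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        doc = {
            "meta": report.meta,
            "per_element": {
                k: json.loads(v.to_json(orient="index"))
                for k, v in report.per_element.items()
            },
            "per_station": json.loads(report.per_station.to_json(orient="index")),
        }
        path.write_text(json.dumps(doc, indent=2, default=str))
    else:
        raise ValueError(f"format must be csv|json, got {fmt!r}")


def read_report(path: str | Path) -> RiskReport:
    """Read back a CSV risk report written by :func:`write_report`."""
    long = pd.read_csv(path, dtype={"station": str, "index": str, "element": str},
                       keep_default_na=False)
    long["value"] = long["value"].astype(float)
    report = RiskReport()
    for name, grp in long.groupby("index", sort=False):
        if (grp["element"] == "").all():
            report.per_station[name] = grp.set_index("station")["value"]
        else:
            report.per_element[name] = (
                grp.pivot(index="station", columns="element", values="value")
                .reindex(index=pd.unique(grp["station"]),
                         columns=pd.unique(grp["element"]))
            )
            report.per_element[name].columns.name = None
    return report
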