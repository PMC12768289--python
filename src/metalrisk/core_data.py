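"""Concentration tables, reference values, and exposure profiles.

Everything downstream — pollution indices, health risk, multivariate source
statistics — consumes the two containers defined here: a
:class:`ConcentrationTable` (sites × elements, one medium, one unit) and a
:class:`ReferenceLibrary` of per-element regulatory limits, geochemical
backgrounds, toxicity factors and dose-response parameters.

Tables are plain delimiter-separated text.  Cells may be bare numbers
(``1.633``) or a ``mean±sd`` pair (``1.633±0.008``); standard deviations are
parsed and retained but the indices operate on means only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationTable",
    "ReferenceLibrary",
    "ExposureProfile",
    "ExceedanceReport",
    "TableFormatError",
    "ValidationError",
    "ConfigurationError",
    "read_concentration_table",
    "write_concentration_table",
    "column_mean",
    "builtin_references",
    "builtin_exposure_profiles",
    "compare_to_limits",
    "MEDIUM_UNITS",
    "LIMIT_SETS",
]

MEDIUM_UNITS = {"water": "µg/L", "sediment": "mg/kg"}

#: Limit-set name -> (library column, medium the limit applies to)
LIMIT_SETS = {
    "ecr": ("mac_ecr", "water"),
    "who": ("mac_who", "water"),
    "usepa": ("mac_usepa", "water"),
    "asv": ("shale_background", "sediment"),
    "trv": ("trv", "sediment"),
    "tel": ("tel", "sediment"),
}


class TableFormatError(ValueError):
    """The input file is not a parseable concentration table."""


class ValidationError(ValueError):
    """The table parsed but violates an invariant (negative value, duplicate site...)."""


class ConfigurationError(ValueError):
    """A reference value or parameter needed for a computation is missing or invalid."""


@dataclass
class ConcentrationTable:
    """Site × element matrix of mean concentrations for one medium.

    Parameters
    ----------
    medium:
        ``"water"`` (µg/L) or ``"sediment"`` (mg/kg).
    values:
        DataFrame indexed by site ID with one column per element symbol.
        All entries must be finite and non-negative.
    sds:
        Optional matching matrix of standard deviations.
    """

    medium: str
    values: pd.DataFrame
    sds: pd.DataFrame | None = None
    units: str = field(init=False)

    def __post_init__(self) -> None:
        if self.medium not in MEDIUM_UNITS:
            raise ValidationError(f"unknown medium {self.medium!r}")
        self.units = MEDIUM_UNITS[self.medium]
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicate site ID(s): {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate element column(s): {dup}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self._locate(~np.isfinite(arr))
            raise ValidationError(f"non-finite concentration at {bad}")
        if (arr < 0).any():
            bad = self._locate(arr < 0)
            raise ValidationError(f"negative concentration at {bad}")
        if self.sds is not None:
            if self.sds.shape != v.shape:
                raise ValidationError("sds shape does not match values")
            self.sds = self.sds.set_axis(v.index, axis=0).set_axis(v.columns, axis=1)

    def _locate(self, mask: np.ndarray) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(mask)
        return [
            (str(self.values.index[r]), str(self.values.columns[c]))
            for r, c in zip(rows, cols)
        ]

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def elements(self) -> list[str]:
        return list(self.values.columns)

    def value(self, site: str, element: str) -> float:
        return float(self.values.at[site, element])

    def site_row(self, site: str) -> pd.Series:
        """One site's concentrations as an element→value Series."""
        return self.values.loc[site]


def _fmt(x: float) -> str:
    return format(float(x), "g")


def read_concentration_table(path: str | Path, medium: str) -> ConcentrationTable:
    """Read a delimiter-separated site × element table.

    The delimiter (comma or tab) is auto-detected from the header.  The first
    column holds site IDs; remaining columns are element symbols (normalized
    to title case).  Cells may be ``mean±sd`` pairs.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty table")
    delim = "\t" if lines[0].count("\t") >= lines[0].count(",") else ","
    header = [h.strip() for h in lines[0].split(delim)]
    if len(header) < 2:
        raise TableFormatError(f"{path}: no element columns found in header {header}")
    elements = [e.title() for e in header[1:]]
    if any(not e for e in elements):
        raise TableFormatError(f"{path}: blank element column name in header")

    sites, means, sds, any_sd = [], [], [], False
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        sites.append(cells[0])
        mrow, srow = [], []
        for el, cell in zip(elements, cells[1:]):
            if "±" in cell:
                m_str, s_str = cell.split("±", 1)
                any_sd = True
            else:
                m_str, s_str = cell, ""
            try:
                m = float(m_str)
                s = float(s_str) if s_str else np.nan
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}:{lineno}: cannot parse cell {cell!r} in column {el}"
                ) from exc
            mrow.append(m)
            srow.append(s)
        means.append(mrow)
        sds.append(srow)

    values = pd.DataFrame(means, index=pd.Index(sites, name="site"), columns=elements)
    sd_frame = (
        pd.DataFrame(sds, index=values.index, columns=elements) if any_sd else None
    )
    return ConcentrationTable(medium=medium, values=values, sds=sd_frame)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write a table in the same dialect :func:`read_concentration_table` reads.

    Round-trips bit-identically: numbers are formatted with the shortest
    ``%g`` representation, and ``mean±sd`` cells are emitted when SDs exist.
    """
    buf = io.StringIO()
    buf.write("site," + ",".join(table.elements) + "\n")
    for site in table.sites:
        cells = []
        for el in table.elements:
            m = _fmt(table.values.at[site, el])
            if table.sds is not None and np.isfinite(table.sds.at[site, el]):
                cells.append(f"{m}±{_fmt(table.sds.at[site, el])}")
            else:
                cells.append(m)
        buf.write(site + "," + ",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def column_mean(table: ConcentrationTable, element: str) -> float:
    """Arithmetic mean of one element across all sites."""
    if element not in table.values.columns:
        raise KeyError(f"element {element!r} not in table")
    return float(table.values[element].mean())


# ---------------------------------------------------------------------------
# Reference library


class ReferenceLibrary:
    """Per-element reference values (limits, backgrounds, toxicity, doses).

    Wraps an element × field DataFrame with NaN marking absent entries.
    Pathway-specific dose parameters fall back to the ingestion value when a
    dermal/inhalation entry is not defined.
    """

    _FALLBACK = {"rfd_derm": "rfd_ing", "rfd_inh": "rfd_ing",
                 "sf_derm": "sf_ing", "sf_inh": "sf_ing"}

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype(float)
        bad = self.table.drop(columns=["ideal"], errors="ignore")
        if (bad <= 0).any().any():
            raise ConfigurationError("reference values must be strictly positive")
        if "ideal" in self.table and (self.table["ideal"] < 0).any():
            raise ConfigurationError("ideal values must be >= 0")

    @classmethod
    def from_mapping(cls, elements: Mapping[str, Mapping[str, float]]) -> "ReferenceLibrary":
        return cls(pd.DataFrame.from_dict(elements, orient="index"))

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]]) -> "ReferenceLibrary":
        """New library with per-element fields replaced; unknown elements are added."""
        table = self.table.copy()
        for el, fields in overrides.items():
            for f, v in fields.items():
                table.loc[el, f] = v
                logger.info("reference override: %s.%s = %s", el, f, v)
        return ReferenceLibrary(table)

    @property
    def elements(self) -> list[str]:
        return list(self.table.index)

    def _column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            return pd.Series(dtype=float)
        return self.table[name].dropna()

    def limits(self, limit_set: str) -> pd.Series:
        """Defined limits for one named set (``ecr``/``who``/``usepa``/``asv``/``trv``/``tel``)."""
        key = limit_set.lower()
        if key not in LIMIT_SETS:
            raise ConfigurationError(
                f"unknown limit set {limit_set!r}; choose from {sorted(LIMIT_SETS)}"
            )
        col = self._column(LIMIT_SETS[key][0])
        if col.empty:
            raise ConfigurationError(f"limit set {limit_set!r} has no defined elements")
        return col

    def mac(self, limit_set: str) -> pd.Series:
        return self.limits(limit_set)

    def ideal(self, element: str) -> float:
        v = self.table.get("ideal", pd.Series(dtype=float)).get(element, np.nan)
        return 0.0 if pd.isna(v) else float(v)

    def background(self, element: str) -> float:
        v = self._column("shale_background").get(element, np.nan)
        if pd.isna(v):
            raise ConfigurationError(f"no shale background for {element}")
        return float(v)

    def backgrounds(self) -> pd.Series:
        return self._column("shale_background")

    def toxic_response(self) -> pd.Series:
        return self._column("toxic_response")

    def rfd(self, element: str, pathway: str) -> float:
        return self._dose("rfd", element, pathway)

    def sf(self, element: str, pathway: str) -> float:
        return self._dose("sf", element, pathway)

    def has_sf(self, element: str) -> bool:
        return pd.notna(self.table.get("sf_ing", pd.Series(dtype=float)).get(element, np.nan))

    def _dose(self, kind: str, element: str, pathway: str) -> float:
        suffix = {"ingestion": "ing", "dermal": "derm", "inhalation": "inh"}.get(pathway)
        if suffix is None:
            raise ConfigurationError(f"unknown pathway {pathway!r}")
        col = f"{kind}_{suffix}"
        v = self.table.get(col, pd.Series(dtype=float)).get(element, np.nan)
        if pd.isna(v) and col in self._FALLBACK:
            v = self.table.get(self._FALLBACK[col], pd.Series(dtype=float)).get(element, np.nan)
        if pd.isna(v):
            raise ConfigurationError(f"no {kind} for {element} via {pathway}")
        return float(v)

    def kp(self, element: str) -> float:
        v = self._column("kp").get(element, np.nan)
        if pd.isna(v):
            raise ConfigurationError(f"no dermal permeability (kp) for {element}")
        return float(v)


@dataclass(frozen=True)
class ExposureProfile:
    """Cohort-specific intake and duration parameters for dose computation."""

    cohort: str
    ir_water: float  # L/day
    exp_freq: float  # days/year
    exp_dur: float  # years
    body_weight: float  # kg
    at_nc: float  # days, non-carcinogenic averaging time
    at_ca: float  # days, carcinogenic averaging time
    skin_area: float  # cm²
    exp_time: float  # h/day
    unit_conv: float = 1e-3  # L/cm³
    ir_inh: float = 20.0  # m³/day
    volatilization: float = 1000.0  # dimensionless attenuation constant

    def __post_init__(self) -> None:
        for name in ("ir_water", "exp_freq", "exp_dur", "body_weight", "at_nc",
                     "at_ca", "skin_area", "exp_time", "unit_conv", "ir_inh",
                     "volatilization"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"exposure.{self.cohort}.{name} must be > 0")
        if self.at_ca < self.at_nc:
            raise ConfigurationError("at_ca must be >= at_nc")


def _load_builtin_yaml() -> dict:
    ref = resources.files("metalrisk.data").joinpath("reference_library.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def builtin_references(overrides: Mapping | str | Path | None = None) -> ReferenceLibrary:
    """The bundled reference library, optionally with overrides.

    ``overrides`` may be a mapping ``{element: {field: value}}`` or a path to
    a YAML file with an ``elements:`` section of the same shape.
    """
    lib = ReferenceLibrary.from_mapping(_load_builtin_yaml()["elements"])
    if overrides is None:
        return lib
    if isinstance(overrides, (str, Path)):
        overrides = yaml.safe_load(Path(overrides).read_text(encoding="utf-8"))
        overrides = overrides.get("elements", overrides)
    return lib.with_overrides(overrides)


def builtin_exposure_profiles() -> dict[str, ExposureProfile]:
    """Bundled adult/child exposure parameter sets."""
    raw = _load_builtin_yaml()["exposure"]
    return {c: ExposureProfile(cohort=c, **params) for c, params in raw.items()}


# ---------------------------------------------------------------------------
# Limit comparison


@dataclass
class ExceedanceReport:
    """Boolean exceedance flags of a table against one limit set."""

    limit_set: str
    limits: pd.Series  # element -> limit, only elements present in both
    flags: pd.DataFrame  # sites × limited elements, True where value > limit
    skipped: list[str]  # elements in the table without a limit in this set

    @property
    def n_exceedances(self) -> int:
        return int(self.flags.to_numpy().sum())

    def exceeding(self) -> list[tuple[str, str]]:
        """(site, element) pairs above the limit."""
        rows, cols = np.nonzero(self.flags.to_numpy())
        return [
            (str(self.flags.index[r]), str(self.flags.columns[c]))
            for r, c in zip(rows, cols)
        ]


def compare_to_limits(
    table: ConcentrationTable, refs: ReferenceLibrary, which: str
) -> ExceedanceReport:
    """Flag every site × element value above the chosen limit set.

    Elements without a limit in the set are skipped and listed in the report.
    """
    limits = refs.limits(which)
    expected = LIMIT_SETS[which.lower()][1]
    if table.medium != expected:
        logger.warning(
            "limit set %s is a %s benchmark but table medium is %s",
            which, expected, table.medium,
        )
    present = [e for e in table.elements if e in limits.index]
    skipped = [e for e in table.elements if e not in limits.index]
    if not present:
        raise ConfigurationError(
            f"limit set {which!r} defines no element present in the table"
        )
    if skipped:
        logger.info("limit set %s: skipping elements without a limit: %s", which, skipped)
    sub = table.values[present]
    flags = sub.gt(limits[present], axis=1)
    return ExceedanceReport(
        limit_set=which.lower(), limits=limits[present], flags=flags, skipped=skipped
    )
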