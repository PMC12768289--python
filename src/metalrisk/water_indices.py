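"""Metal pollution indices for surface water: HPI, HEI and degree of contamination.

All three indices compare measured concentrations ``C_i`` (µg/L) against a
maximum admissible concentration ``S_i`` from a chosen regulatory limit set:

* ``HPI = Σ W_i Q_i / Σ W_i`` with weights ``W_i = k / S_i`` and sub-indices
  ``Q_i = 100 |C_i − I_i| / (S_i − I_i)``, where ``I_i`` is the ideal value
  (0 by default).  A single element at its standard scores exactly 100.
* ``HEI = Σ C_i / S_i`` — a plain sum of concentration-to-standard ratios.
* ``C_d = Σ (C_i / S_i − 1) = HEI − n`` — HEI shifted by the number of
  elements used; negative values mean concentrations sit below standards.

Classification bands: HPI <15 low / 15–30 medium / >30 high; HEI <10 low /
10–20 medium / >20 significant; water with HEI below 1.0 is additionally
labelled fit for domestic use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_data import (
    ConcentrationTable,
    ConfigurationError,
    ReferenceLibrary,
)

__all__ = [
    "WaterIndexResult",
    "hpi",
    "hei",
    "degree_of_contamination",
    "classify_hpi",
    "classify_hei",
    "fitness",
    "water_index_table",
]


@dataclass
class WaterIndexResult:
    site: str
    hpi: float
    hei: float
    c_deg: float
    hpi_class: str
    hei_class: str
    fitness: str
    elements_used: list[str]


def _usable(site_row: pd.Series, refs: ReferenceLibrary, limit_set: str) -> pd.Series:
    """Standards for the elements of this row that have one; error if none."""
    mac = refs.limits(limit_set)
    mac = mac[mac.index.intersection(site_row.index)]
    if mac.empty:
        raise ConfigurationError(
            f"no element of this row has a standard in limit set {limit_set!r}"
        )
    return mac


def hpi(
    site_row: pd.Series,
    refs: ReferenceLibrary,
    limit_set: str = "ecr",
    k: float = 1.0,
) -> float:
    """Heavy-metal pollution index of one site row (element → µg/L)."""
    mac = _usable(site_row, refs, limit_set)
    num = den = 0.0
    for el, s in mac.items():
        ideal = refs.ideal(el)
        if s == ideal:
            raise ConfigurationError(
                f"standard equals ideal value for {el}; HPI sub-index undefined"
            )
        w = k / s
        q = 100.0 * abs(site_row[el] - ideal) / (s - ideal)
        num += w * q
        den += w
    return num / den


def hei(site_row: pd.Series, refs: ReferenceLibrary, limit_set: str = "ecr") -> float:
    """Heavy-metal evaluation index: Σ C_i / MAC_i over elements with a standard."""
    mac = _usable(site_row, refs, limit_set)
    return float((site_row[mac.index] / mac).sum())


def degree_of_contamination(
    site_row: pd.Series, refs: ReferenceLibrary, limit_set: str = "ecr"
) -> float:
    """C_d = Σ (C_i/MAC_i − 1); equals HEI minus the element count used."""
    mac = _usable(site_row, refs, limit_set)
    return float((site_row[mac.index] / mac - 1.0).sum())


def classify_hpi(value: float) -> str:
    if value < 15:
        return "low"
    if value <= 30:
        return "medium"
    return "high"


def classify_hei(value: float) -> str:
    if value < 10:
        return "low"
    if value <= 20:
        return "medium"
    return "significant"


def fitness(hei_value: float) -> str:
    """Domestic-use verdict at the HEI threshold of 1.0."""
    return "fit" if hei_value < 1.0 else "unfit"


def water_index_table(
    table: ConcentrationTable,
    refs: ReferenceLibrary,
    limit_set: str = "ecr",
    k: float = 1.0,
) -> pd.DataFrame:
    """All three indices plus class labels for every site of a water table."""
    rows = []
    for site in table.sites:
        row = table.site_row(site)
        mac = _usable(row, refs, limit_set)
        h = hpi(row, refs, limit_set, k=k)
        e = hei(row, refs, limit_set)
        rows.append(
            WaterIndexResult(
                site=site,
                hpi=h,
                hei=e,
                c_deg=e - len(mac),
                hpi_class=classify_hpi(h),
                hei_class=classify_hei(e),
                fitness=fitness(e),
                elements_used=list(mac.index),
            )
        )
    out = pd.DataFrame(
        {
            "hpi": [r.hpi for r in rows],
            "hei": [r.hei for r in rows],
            "c_deg": [r.c_deg for r in rows],
            "hpi_class": [r.hpi_class for r in rows],
            "hei_class": [r.hei_class for r in rows],
            "fitness": [r.fitness for r in rows],
            "n_elements": [len(r.elements_used) for r in rows],
        },
        index=pd.Index([r.site for r in rows], name="site"),
    )
    return out
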