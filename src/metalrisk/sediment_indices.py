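"""Geochemical contamination indices for sediment.

Per site × element, against an average-shale background ``B``:

* geoaccumulation index  ``Igeo = log₂(C / (1.5 B))`` — the 1.5 factor
  absorbs natural lithologic variability;
* enrichment factor      ``EF = (C_x/C_ref) / (B_x/B_ref)`` normalised to a
  conservative reference element (Mn by default);
* contamination factor   ``CF = C / B``.

Per site:

* pollution load index   ``PLI = (Π CF)^(1/n)`` — geometric mean of the CFs;
* potential ecological risk ``PER = Σ T_r · CF`` over elements with a
  Hakanson toxic-response factor ``T_r``, banded low (<110), moderate
  (110–200), considerable (200–400) and very high (≥400).

Concentrations are also screened against the USEPA sediment-toxicity bands
(non/moderately/heavily polluted) for Pb, Cu, As, Cd, Ni and Mn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ConcentrationTable, ConfigurationError, ReferenceLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "igeo",
    "enrichment_factor",
    "contamination_factor",
    "pollution_load_index",
    "potential_ecological_risk",
    "usepa_sediment_class",
    "classify_igeo",
    "classify_ef",
    "classify_cf",
    "classify_per",
    "SedimentIndexResult",
    "sediment_index_table",
    "USEPA_SEDIMENT_BANDS",
]

#: element -> (non/moderate cut, moderate/heavy cut); None = no lower bands defined.
USEPA_SEDIMENT_BANDS = {
    "Pb": (40.0, 60.0),
    "Cu": (25.0, 50.0),
    "As": (3.0, 8.0),
    "Cd": (None, 6.0),
    "Ni": (20.0, 50.0),
    "Mn": (300.0, 500.0),
}


def igeo(c: float, b: float) -> float:
    """Geoaccumulation index log₂(C/(1.5·B)); −inf for C = 0 (uncontaminated)."""
    if b <= 0:
        raise ValueError("background must be > 0")
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c == 0:
        logger.info("igeo: zero concentration reported as uncontaminated (-inf)")
        return -math.inf
    return math.log2(c / (1.5 * b))


def enrichment_factor(c_x: float, c_ref: float, b_x: float, b_ref: float) -> float:
    """EF = (C_x/C_ref) / (B_x/B_ref); ≡ 1 for the reference element itself."""
    if c_ref <= 0:
        raise ValueError("reference-element concentration must be > 0")
    if b_x <= 0 or b_ref <= 0:
        raise ValueError("backgrounds must be > 0")
    if c_x < 0:
        raise ValueError("concentration must be >= 0")
    return (c_x / c_ref) / (b_x / b_ref)


def contamination_factor(c: float, b: float) -> float:
    """CF = C / B."""
    if b <= 0:
        raise ValueError("background must be > 0")
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return c / b


def pollution_load_index(cf_values) -> float:
    """Geometric mean of contamination factors; requires every CF > 0."""
    cf = np.asarray(list(cf_values), dtype=float)
    if cf.size == 0:
        raise ValueError("PLI needs at least one contamination factor")
    if (cf <= 0).any():
        raise ValueError(
            "PLI undefined for zero contamination factors; exclude those elements"
        )
    return float(np.exp(np.mean(np.log(cf))))


def potential_ecological_risk(
    cf: pd.Series, tr: pd.Series
) -> tuple[float, str, list[str]]:
    """PER = Σ T_r·CF over elements with a toxic-response factor.

    Returns (value, class label, elements excluded for lack of a factor).
    """
    used = [e for e in cf.index if e in tr.index]
    excluded = [e for e in cf.index if e not in tr.index]
    if excluded:
        logger.info("PER: excluding elements without a toxic-response factor: %s", excluded)
    if not used:
        raise ConfigurationError("no element has a toxic-response factor")
    value = float((tr[used] * cf[used]).sum())
    return value, classify_per(value), excluded


def usepa_sediment_class(element: str, c: float) -> str:
    """USEPA sediment-toxicity class for Pb, Cu, As, Cd, Ni or Mn."""
    if element not in USEPA_SEDIMENT_BANDS:
        raise ConfigurationError(
            f"no USEPA sediment classification for {element}; "
            f"supported: {sorted(USEPA_SEDIMENT_BANDS)}"
        )
    low, high = USEPA_SEDIMENT_BANDS[element]
    if c > high:
        return "heavily_polluted"
    if low is not None and c >= low:
        return "moderately_polluted"
    return "non_polluted"


def classify_igeo(v: float) -> str:
    bands = [
        (0, "uncontaminated"),
        (1, "uncontaminated_to_moderate"),
        (2, "moderate"),
        (3, "moderate_to_heavy"),
        (4, "heavy"),
        (5, "heavy_to_extreme"),
    ]
    for cut, label in bands:
        if v <= cut:
            return label
    return "extreme"


def classify_ef(v: float) -> str:
    if v < 1:
        return "no_enrichment"
    if v < 3:
        return "minor"
    if v < 5:
        return "moderate"
    if v < 10:
        return "moderately_severe"
    if v < 25:
        return "severe"
    if v < 50:
        return "very_severe"
    return "extremely_severe"


def classify_cf(v: float) -> str:
    if v < 1:
        return "low"
    if v < 3:
        return "moderate"
    if v < 6:
        return "considerable"
    return "very_high"


def classify_per(v: float) -> str:
    if v < 110:
        return "low"
    if v < 200:
        return "moderate"
    if v < 400:
        return "considerable"
    return "very_high"


@dataclass
class SedimentIndexResult:
    site: str
    igeo: pd.Series
    ef: pd.Series
    cf: pd.Series
    pli: float
    per: float
    per_class: str
    usepa_class: pd.Series  # only the six classified elements present


def sediment_index_table(
    table: ConcentrationTable,
    refs: ReferenceLibrary,
    reference_element: str = "Mn",
) -> list[SedimentIndexResult]:
    """Every index for every site of a sediment table.

    EF is normalised to ``reference_element``; PLI uses all elements with a
    background; PER uses the elements with a toxic-response factor.
    """
    if reference_element not in table.elements:
        raise ConfigurationError(
            f"reference element {reference_element!r} not in table"
        )
    b = refs.backgrounds()
    missing = [e for e in table.elements if e not in b.index]
    if missing:
        raise ConfigurationError(f"no shale background for: {missing}")
    tr = refs.toxic_response()
    b_ref = refs.background(reference_element)

    results = []
    for site in table.sites:
        row = table.site_row(site)
        c_ref = float(row[reference_element])
        if c_ref <= 0:
            raise ValueError(
                f"reference element {reference_element} is zero at site {site}"
            )
        cf = pd.Series(
            {e: contamination_factor(row[e], b[e]) for e in table.elements}
        )
        ig = pd.Series({e: igeo(row[e], b[e]) for e in table.elements})
        ef = pd.Series(
            {
                e: enrichment_factor(row[e], c_ref, b[e], b_ref)
                for e in table.elements
            }
        )
        per, per_class, _ = potential_ecological_risk(cf, tr)
        usepa = pd.Series(
            {
                e: usepa_sediment_class(e, row[e])
                for e in table.elements
                if e in USEPA_SEDIMENT_BANDS
            }
        )
        results.append(
            SedimentIndexResult(
                site=site,
                igeo=ig,
                ef=ef,
                cf=cf,
                pli=pollution_load_index(cf),
                per=per,
                per_class=per_class,
                usepa_class=usepa,
            )
        )
    return results


def sediment_long_table(results: list[SedimentIndexResult]) -> pd.DataFrame:
    """Tidy site × element × index frame plus per-site PLI/PER rows."""
    rows = []
    for r in results:
        for e in r.cf.index:
            rows.append(
                {
                    "site": r.site, "element": e,
                    "igeo": r.igeo[e], "igeo_class": classify_igeo(r.igeo[e]),
                    "ef": r.ef[e], "ef_class": classify_ef(r.ef[e]),
                    "cf": r.cf[e], "cf_class": classify_cf(r.cf[e]),
                    "usepa_class": r.usepa_class.get(e, ""),
                }
            )
    long = pd.DataFrame(rows)
    per_site = pd.DataFrame(
        {
            "site": [r.site for r in results],
            "pli": [r.pli for r in results],
            "per": [r.per for r in results],
            "per_class": [r.per_class for r in results],
        }
    )
    return long.merge(per_site, on="site")
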