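"""Deterministic USEPA-style human-health risk from trace elements in water.

Chronic daily intake (CDI, mg/kg/day) is computed per element and exposure
pathway from a cohort :class:`~metalrisk.core_data.ExposureProfile`:

* ingestion:  ``C · IR · EF · ED / (BW · AT)``
* dermal:     ``C · SA · Kp · ET · EF · ED · CF / (BW · AT)``
* inhalation: ``C · IR_inh · EF · ED / (K · BW · AT)``

with ``C`` the concentration converted to mg/L, ``CF`` the 10⁻³ L/cm³ volume
conversion and ``K`` a dimensionless volatilization attenuation constant for
the water-to-air pathway.  Non-carcinogenic risk uses the averaging time
``at_nc``; carcinogenic risk uses ``at_ca``.

Hazard quotient HQ = CDI/RfD (acceptable below 1), hazard index
HI = Σ_pathway HQ, carcinogenic risk CR = CDI·SF for the elements with a
published slope factor (As, Pb, Cd, Cr, Ni here) and TCR = Σ CR, judged
against the conventional 10⁻⁶–10⁻⁴ acceptability band.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_data import (
    ConcentrationTable,
    ConfigurationError,
    ExposureProfile,
    ReferenceLibrary,
)

__all__ = [
    "PATHWAYS",
    "DEFAULT_CARCINOGENS",
    "RiskResult",
    "cdi",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "total_cr",
    "classify_cr",
    "site_risk",
    "risk_summary",
]

PATHWAYS = ("ingestion", "dermal", "inhalation")

#: Elements with an available carcinogenic slope factor.
DEFAULT_CARCINOGENS = ("As", "Pb", "Cd", "Cr", "Ni")

_UG_PER_L_TO_MG_PER_L = 1e-3


class UnsupportedElementError(ConfigurationError):
    """Carcinogenic risk requested for an element without a slope factor."""


def cdi(
    conc_ug_l: float,
    pathway: str,
    profile: ExposureProfile,
    kp: float | None = None,
    carcinogenic: bool = False,
) -> float:
    """Chronic daily intake (mg/kg/day) of one element via one pathway.

    ``kp`` (cm/h) is required for the dermal pathway.  ``carcinogenic``
    selects the carcinogenic averaging time ``at_ca`` instead of ``at_nc``.
    """
    c = conc_ug_l * _UG_PER_L_TO_MG_PER_L
    at = profile.at_ca if carcinogenic else profile.at_nc
    duration = profile.exp_freq * profile.exp_dur / (profile.body_weight * at)
    if pathway == "ingestion":
        return c * profile.ir_water * duration
    if pathway == "dermal":
        if kp is None:
            raise ConfigurationError("dermal CDI requires a permeability coefficient kp")
        return (
            c * profile.skin_area * kp * profile.exp_time * profile.unit_conv * duration
        )
    if pathway == "inhalation":
        return c * profile.ir_inh / profile.volatilization * duration
    raise ConfigurationError(f"unknown pathway {pathway!r}")


def hazard_quotient(cdi_value: float, rfd: float) -> float:
    """HQ = CDI / RfD."""
    if rfd <= 0:
        raise ConfigurationError("reference dose must be > 0")
    return cdi_value / rfd


def hazard_index(hq_by_pathway) -> float:
    """HI = Σ HQ over pathways."""
    return float(sum(hq_by_pathway))


def carcinogenic_risk(cdi_value: float, sf: float) -> float:
    """CR = CDI · SF."""
    if sf <= 0:
        raise ConfigurationError("slope factor must be > 0")
    return cdi_value * sf


def total_cr(cr_by_element) -> float:
    """TCR = Σ CR over carcinogenic elements."""
    return float(sum(cr_by_element))


def classify_cr(tcr: float) -> str:
    """Acceptability band for a lifetime carcinogenic risk."""
    if tcr < 0:
        raise ValueError("carcinogenic risk cannot be negative")
    if tcr < 1e-6:
        return "below_range"
    if tcr <= 1e-4:
        return "acceptable"
    return "above_range"


@dataclass
class RiskResult:
    """Per-site risk bundle for one cohort."""

    site: str
    cohort: str
    cdi: pd.DataFrame  # element × pathway, non-carcinogenic averaging
    hq: pd.DataFrame  # element × pathway
    hi: pd.Series  # element → Σ pathway HQ
    cr: pd.Series  # carcinogenic elements → CDI_ca · SF (summed over pathways)
    tcr: float
    tcr_class: str


def site_risk(
    site_row: pd.Series,
    refs: ReferenceLibrary,
    profile: ExposureProfile,
    pathways: tuple[str, ...] = PATHWAYS,
    carcinogens: tuple[str, ...] = DEFAULT_CARCINOGENS,
    site: str = "",
) -> RiskResult:
    """Full deterministic risk computation for one site row (element → µg/L)."""
    elements = list(site_row.index)
    cdi_m = pd.DataFrame(index=elements, columns=list(pathways), dtype=float)
    hq_m = pd.DataFrame(index=elements, columns=list(pathways), dtype=float)
    for el in elements:
        for pw in pathways:
            kp = refs.kp(el) if pw == "dermal" else None
            d = cdi(site_row[el], pw, profile, kp=kp)
            cdi_m.at[el, pw] = d
            hq_m.at[el, pw] = hazard_quotient(d, refs.rfd(el, pw))
    hi = hq_m.sum(axis=1)

    cr = {}
    for el in carcinogens:
        if el not in elements:
            continue
        if not refs.has_sf(el):
            raise UnsupportedElementError(f"no carcinogenic slope factor for {el}")
        cr[el] = total_cr(
            carcinogenic_risk(
                cdi(site_row[el], pw, profile,
                    kp=refs.kp(el) if pw == "dermal" else None,
                    carcinogenic=True),
                refs.sf(el, pw),
            )
            for pw in pathways
        )
    cr_s = pd.Series(cr, dtype=float)
    tcr = total_cr(cr_s)
    return RiskResult(
        site=site,
        cohort=profile.cohort,
        cdi=cdi_m,
        hq=hq_m,
        hi=hi,
        cr=cr_s,
        tcr=tcr,
        tcr_class=classify_cr(tcr),
    )


def risk_summary(
    table: ConcentrationTable,
    refs: ReferenceLibrary,
    profiles: dict[str, ExposureProfile],
    pathways: tuple[str, ...] = PATHWAYS,
    carcinogens: tuple[str, ...] = DEFAULT_CARCINOGENS,
) -> pd.DataFrame:
    """Long-format site × cohort summary: max HQ, total HI, TCR and its band."""
    rows = []
    for cohort, profile in profiles.items():
        for site in table.sites:
            r = site_risk(
                table.site_row(site), refs, profile,
                pathways=pathways, carcinogens=carcinogens, site=site,
            )
            rows.append(
                {
                    "site": site,
                    "cohort": cohort,
                    "max_hq": float(r.hq.max().max()),
                    "max_hq_element": str(r.hi.idxmax()),
                    "hi_total": float(r.hi.sum()),
                    "tcr": r.tcr,
                    "tcr_class": r.tcr_class,
                }
            )
    return pd.DataFrame(rows)
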