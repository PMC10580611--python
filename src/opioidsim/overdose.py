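"""Overdose hazard and fatal/non-fatal resolution.

Exposure (MME dose, opioid type, treatment/diversion status) is converted
into a daily overdose probability; an overdose resolves through a naloxone
availability draw, a reversal draw, and a conditional-fatality draw.

Person-year rates and annual probabilities from the parameter table are
applied at daily steps through exponential-hazard transforms:

    daily = 1 - exp(-rate / 36,500)          (rate per 100 person-years)
    daily = 1 - (1 - annual) ** (1 / 365)    (annual probability)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import OverdoseHazardParams
from .states import Modality, OpioidType

DAYS_PER_YEAR = 365


def rate_to_daily_prob(rate_per_100py):
    """Convert a rate per 100 person-years to a daily event probability.

    Accepts scalars or arrays; monotone increasing, and approximately
    ``rate / 36,500`` for small rates.
    """
    rate = np.asarray(rate_per_100py, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate per 100 person-years must be non-negative")
    out = -np.expm1(-rate / (100.0 * DAYS_PER_YEAR))
    return float(out) if out.ndim == 0 else out


def annual_to_daily_prob(annual_prob):
    """Convert an annual probability to the equivalent daily probability.

    365 independent daily draws then reproduce the annual probability:
    ``1 - (1 - daily) ** 365 == annual``.
    """
    p = np.asarray(annual_prob, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("annual probability must lie in [0, 1]")
    if np.any(p == 1.0):
        raise ValueError("annual probability of exactly 1 has no daily equivalent")
    out = -np.expm1(np.log1p(-p) / DAYS_PER_YEAR)
    return float(out) if out.ndim == 0 else out


def mme_band_index(mme, params: OverdoseHazardParams):
    """Index of the MME risk band (<20, 20-49, 50-99, >=100 by default)."""
    mme_arr = np.asarray(mme, dtype=float)
    if np.any(mme_arr < 0):
        raise ValueError("MME must be non-negative")
    idx = np.searchsorted(np.asarray(params.mme_band_edges, dtype=float),
                          mme_arr, side="right")
    return int(idx) if idx.ndim == 0 else idx


def po_daily_hazard(mme, params: OverdoseHazardParams, heroin=False):
    """Daily overdose probability for prescription-opioid exposure at ``mme``.

    The heroin/fentanyl multiplier (1.7) applies on top of the dose band.
    Vectorized over ``mme`` and the boolean ``heroin``.
    """
    ratios = np.asarray(params.band_hazard_ratios, dtype=float)
    h = params.base_daily_hazard * ratios[mme_band_index(mme, params)]
    h = np.where(np.asarray(heroin), h * params.heroin_od_multiplier, h)
    out = np.minimum(h, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class Exposure:
    """One agent-day of opioid exposure, the input to ``daily_overdose_prob``."""

    opioid_type: OpioidType = OpioidType.NONE
    mme: float = 0.0
    modality: int | None = None  # Modality value when on MOUD
    days_in_treatment: int = 0
    naltrexone_recent_days: int = 30


def daily_overdose_prob(exposure: Exposure, params: OverdoseHazardParams,
                        treatment=None) -> float:
    """Daily overdose probability for one agent-day.

    Prescription opioids follow the banded dose-response; heroin/fentanyl
    multiplies it by 1.7; MOUD and diverted-buprenorphine days override the
    dose-based hazard with the modality's person-year rate; no exposure
    means zero hazard.  ``treatment`` supplies the modality rates and
    defaults to the standard :class:`~opioidsim.params.TreatmentParams`.
    """
    if exposure.mme < 0:
        raise ValueError("MME must be non-negative")
    if treatment is None:
        from .params import TreatmentParams
        treatment = TreatmentParams()
    t = exposure.opioid_type
    if t == OpioidType.NONE:
        return 0.0
    if t == OpioidType.MOUD:
        if exposure.modality == Modality.METHADONE:
            return rate_to_daily_prob(treatment.od_rate_methadone)
        if exposure.modality == Modality.BUPRENORPHINE:
            return rate_to_daily_prob(treatment.od_rate_bupe)
        if exposure.modality == Modality.NALTREXONE:
            if exposure.days_in_treatment < treatment.naltrexone_recent_days:
                return rate_to_daily_prob(treatment.od_rate_naltrexone_recent)
            # past the protective window the episode lapses for risk purposes;
            # the agent's off-treatment (dose-based) hazard applies instead
            return po_daily_hazard(exposure.mme, params)
        raise ValueError(f"unknown MOUD modality {exposure.modality!r}")
    if t in (OpioidType.DIVERTED_BUPE, OpioidType.NAIVE_BUPE):
        return rate_to_daily_prob(params.od_rate_diverted_bupe)
    if t == OpioidType.HEROIN_FENTANYL:
        return po_daily_hazard(exposure.mme, params, heroin=True)
    if t in (OpioidType.PRESCRIBED_PO, OpioidType.ILLICIT_PO):
        return po_daily_hazard(exposure.mme, params)
    raise ValueError(f"unknown opioid type {t!r}")


@dataclass
class OverdoseEvent:
    """One overdose occurrence and its resolution."""

    agent_id: int
    day: int
    opioid_type: OpioidType
    naloxone_available: bool
    reversed: bool
    fatal: bool

    def __post_init__(self) -> None:
        if self.reversed and not self.naloxone_available:
            raise ValueError("an overdose cannot be reversed without naloxone")
        if self.reversed and self.fatal:
            raise ValueError("a reversed overdose cannot be fatal")


def fatality_probability(opioid_type: OpioidType,
                         params: OverdoseHazardParams) -> float:
    """Conditional fatality for a non-reversed overdose of the given type."""
    p = params.p_fatal_given_od
    if opioid_type == OpioidType.HEROIN_FENTANYL:
        p = p * params.heroin_fatal_multiplier
    return min(1.0, p)


def resolve_overdose(agent_id: int, day: int, opioid_type: OpioidType,
                     params: OverdoseHazardParams,
                     rng: np.random.Generator) -> OverdoseEvent:
    """Resolve one overdose to fatal or non-fatal.

    Naloxone is drawn per event; if available and the reversal draw
    succeeds the event is non-fatal.  Otherwise the conditional fatality
    (0.17, times 1.5 for heroin/fentanyl) decides.  With
    ``fatal_prob_is_marginal`` the conditional fatality applies to every
    overdose and naloxone mechanics only act through the reversal path.
    """
    naloxone = bool(rng.random() < params.p_naloxone_available)
    reversed_ = bool(naloxone and rng.random() < params.p_reversal_given_naloxone)
    if reversed_:
        fatal = False
    else:
        fatal = bool(rng.random() < fatality_probability(opioid_type, params))
    return OverdoseEvent(agent_id=agent_id, day=day, opioid_type=opioid_type,
                         naloxone_available=naloxone, reversed=reversed_,
                         fatal=fatal)
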