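"""Pain onset, physician prescribing and refills, and the misuse /
dependence transitions that seed opioid use disorder.

Annual probabilities from the parameter table are applied at daily
resolution through ``annual_to_daily_prob``; dose draws are truncated
normals with a 1 MME floor; a cap-compliant physician (92.7%) never lets
a dose reach 90 MME/day; a PDMP-compliant physician (77.5%) refuses a
prescription when the patient already holds another active one.

Misuse and dependence are per-agent *lifetime* propensities (uniform on
8-16% and 2-14% of those ever prescribed), decided once at the end of the
agent's first prescription course; dependence is nested within the misuse
pathway.  Dependent agents cut off from prescription supply for a run of
days may escalate to heroin/fentanyl.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .overdose import annual_to_daily_prob
from .params import PrescribingParams
from .population import Population
from .states import Pain, UseState, oud_active_mask


@dataclass
class Prescription:
    """One opioid prescription course."""

    daily_dose: float  # MME/day
    days_remaining: int
    pain_type: Pain
    refill_count: int = 0

    def __post_init__(self) -> None:
        if self.daily_dose <= 0:
            raise ValueError("daily_dose must be positive")
        if self.days_remaining < 0:
            raise ValueError("days_remaining must be non-negative")

    @property
    def active(self) -> bool:
        return self.days_remaining > 0


@dataclass
class Physician:
    """Per-physician behavior (drawn once per agent at initialization)."""

    p_refill_acute: float = 0.25
    p_refill_chronic: float = 0.90
    cap_compliant: bool = True
    pdmp_compliant: bool = True


class RefillDecision(Enum):
    REFILL = "refill"
    REFILL_WITH_ESCALATION = "refill_with_escalation"
    DENY = "deny"


def sample_pain_onset(agent, params: PrescribingParams,
                      rng: np.random.Generator):
    """Draw today's acute-pain onset for one pain-free agent.

    The 15%/12-month figure becomes the daily probability
    ``1 - (1 - 0.15)**(1/365)``.  Chronic pain is assigned at
    initialization by prevalence and persists, so it is never drawn here.
    Returns ``Pain.ACUTE`` on onset, else ``None``.
    """
    if not agent.alive:
        raise RuntimeError("dead agents do not develop pain")
    if agent.pain != Pain.NONE:
        return None
    p_daily = annual_to_daily_prob(params.p_acute_pain_12mo)
    return Pain.ACUTE if rng.random() < p_daily else None


def _draw_dose(pain_type: Pain, params: PrescribingParams,
               rng: np.random.Generator, cap_compliant: bool) -> float:
    if pain_type == Pain.ACUTE:
        mean, sd = params.acute_dose_mean, params.acute_dose_sd
    elif pain_type == Pain.CHRONIC:
        mean, sd = params.chronic_dose_mean, params.chronic_dose_sd
    else:
        raise ValueError(f"cannot prescribe for pain type {pain_type!r}")
    dose = max(params.dose_floor_mme, float(rng.normal(mean, sd)))
    if cap_compliant:
        dose = min(dose, params.dose_cap_mme - 1e-9)
    return dose


def _draw_length(pain_type: Pain, params: PrescribingParams,
                 rng: np.random.Generator) -> int:
    if pain_type == Pain.ACUTE:
        lo, hi = params.acute_len_min_days, params.acute_len_max_days
    else:
        lo, hi = params.chronic_len_min_days, params.chronic_len_max_days
    return int(rng.integers(lo, hi + 1))


def issue_prescription(pain_type: Pain, params: PrescribingParams,
                       rng: np.random.Generator,
                       physician: Physician | None = None,
                       has_other_active_rx: bool = False):
    """Issue (or not) a prescription for a presenting patient.

    The receive probability is 22% for acute and 30% for chronic pain; the
    dose is a truncated normal (30/10 or 50/10 MME), clamped below 90
    MME/day when the physician honors the dosage cap; a PDMP-compliant
    physician refuses if the patient already holds an active prescription.
    """
    physician = physician or Physician()
    if pain_type == Pain.ACUTE:
        p_receive = params.p_rx_given_acute
    elif pain_type == Pain.CHRONIC:
        p_receive = params.p_rx_given_chronic
    else:
        raise ValueError(f"cannot prescribe for pain type {pain_type!r}")
    if physician.pdmp_compliant and has_other_active_rx:
        return None
    if rng.random() >= p_receive:
        return None
    return Prescription(
        daily_dose=_draw_dose(pain_type, params, rng, physician.cap_compliant),
        days_remaining=_draw_length(pain_type, params, rng),
        pain_type=pain_type,
    )


def refill_decision(rx: Prescription, still_in_pain: bool,
                    physician: Physician, params: PrescribingParams,
                    rng: np.random.Generator,
                    has_other_active_rx: bool = False) -> RefillDecision:
    """Physician decision on an expiring prescription.

    Refills are granted with the physician's per-type probability (acute
    mean 25%, chronic mean 90%, each with 10% between-physician SD); a
    granted refill carries a dose escalation with probability
    ``p_escalate_on_refill``; PDMP-compliant physicians deny when the
    patient holds an overlapping prescription; no reported pain means no
    refill.
    """
    if not still_in_pain:
        return RefillDecision.DENY
    if physician.pdmp_compliant and has_other_active_rx:
        return RefillDecision.DENY
    p = physician.p_refill_acute if rx.pain_type == Pain.ACUTE \
        else physician.p_refill_chronic
    u = rng.random()
    if u >= p:
        return RefillDecision.DENY
    if u < p * params.p_escalate_on_refill:
        return RefillDecision.REFILL_WITH_ESCALATION
    return RefillDecision.REFILL


def apply_refill(rx: Prescription, decision: RefillDecision,
                 params: PrescribingParams, rng: np.random.Generator,
                 cap_compliant: bool = True,
                 escalation_fraction: float | None = None) -> Prescription | None:
    """Renew a prescription according to a refill decision.

    On escalation the daily dose rises by a normal fraction with mean 25%;
    a cap-compliant physician still clamps the result below 90 MME/day.
    Returns the renewed prescription, or ``None`` on denial.
    """
    if decision == RefillDecision.DENY:
        return None
    dose = rx.daily_dose
    if decision == RefillDecision.REFILL_WITH_ESCALATION:
        frac = escalation_fraction if escalation_fraction is not None else \
            max(0.0, float(rng.normal(params.dose_escalation_mean,
                                      params.dose_escalation_sd)))
        dose = dose * (1.0 + frac)
    if cap_compliant:
        dose = min(dose, params.dose_cap_mme - 1e-9)
    return Prescription(daily_dose=dose,
                        days_remaining=_draw_length(rx.pain_type, params, rng),
                        pain_type=rx.pain_type,
                        refill_count=rx.refill_count + 1)


def draw_misuse_flags(misuse_prop, dependence_prop, u):
    """Lifetime misuse / dependence outcome from one uniform draw.

    ``misuse = u < misuse_prop`` and ``dependence = u < min(dependence_prop,
    misuse_prop)``, so dependence is nested within misuse and the marginal
    dependence probability equals ``min(dependence_prop, misuse_prop)``.
    Vectorized.
    """
    misuse = u < misuse_prop
    depend = u < np.minimum(dependence_prop, misuse_prop)
    return misuse, depend


def misuse_transition(pop: Population, i: int, params: PrescribingParams,
                      rng: np.random.Generator) -> UseState:
    """Resolve the lifetime misuse/dependence draw for agent ``i``.

    Called at the end of the agent's first prescription course; later
    courses never re-draw.  Returns the agent's (possibly updated) state.
    """
    if not pop.first_course_done[i]:
        misuse, depend = draw_misuse_flags(pop.misuse_prop[i],
                                           pop.dependence_prop[i], rng.random())
        pop.first_course_done[i] = True
        pop.will_misuse[i] = misuse
        pop.will_depend[i] = depend
        if misuse and pop.use_state[i] == UseState.PRESCRIBED_PO:
            pop.use_state[i] = UseState.MISUSE_PO
    return UseState(int(pop.use_state[i]))


# ---------------------------------------------------------------------------
# vectorized daily step
# ---------------------------------------------------------------------------


def step_prescribing(pop: Population, params: PrescribingParams, u: dict,
                     dosing: np.random.Generator) -> None:
    """One day of pain onset, prescribing, refills, and OUD transitions.

    ``u`` maps aligned purpose names to population-length uniform arrays
    for today; ``dosing`` is the event-driven generator for dose and
    course-length draws.
    """
    n = pop.n
    alive = pop.alive
    in_tx = pop.use_state == UseState.IN_TREATMENT
    p_onset = annual_to_daily_prob(params.p_acute_pain_12mo)

    # --- acute pain onset and resolution
    onset = alive & ~in_tx & (pop.pain == Pain.NONE) & (u["pain"] < p_onset)
    pop.pain[onset] = Pain.ACUTE
    pop.acute_days_left[onset] = params.acute_pain_duration_days
    ongoing = pop.acute_days_left > 0
    pop.acute_days_left[ongoing] -= 1
    resolved = ongoing & (pop.acute_days_left == 0) & (pop.pain == Pain.ACUTE)
    pop.pain[resolved] = Pain.NONE

    # --- new acute prescriptions at presentation (onset day)
    receive = onset & (u["rx_acute"] < params.p_rx_given_acute)
    receive &= ~(pop.phys_pdmp_compliant & (pop.rx_days_c > 0))
    _issue_vector(pop, receive, Pain.ACUTE, params, dosing)

    # --- chronic-pain re-presentation (untreated chronic pain, no script)
    p_chronic = (1.0 / params.chronic_present_interval_days) * params.p_rx_given_chronic
    present = alive & ~in_tx & (pop.pain == Pain.CHRONIC) & (pop.rx_days_c == 0) \
        & (u["rx_chronic"] < p_chronic)
    present &= ~(pop.phys_pdmp_compliant & (pop.rx_days_a > 0))
    _issue_vector(pop, present, Pain.CHRONIC, params, dosing)

    # --- countdown and refills
    course_end = np.zeros(n, dtype=bool)
    for slot, pain_type in (("a", Pain.ACUTE), ("c", Pain.CHRONIC)):
        days = getattr(pop, f"rx_days_{slot}")
        dose = getattr(pop, f"rx_dose_{slot}")
        refills = getattr(pop, f"rx_refills_{slot}")
        active = days > 0
        days[active] -= 1
        expired = active & (days == 0)
        course_end |= expired
        if pain_type == Pain.ACUTE:
            still_in_pain = pop.pain == Pain.ACUTE
            p_refill = pop.phys_refill_acute
            other_active = pop.rx_days_c > 0
            uu = u["refill_acute"]
        else:
            still_in_pain = pop.pain == Pain.CHRONIC
            p_refill = pop.phys_refill_chronic
            other_active = pop.rx_days_a > 0
            uu = u["refill_chronic"]
        can_refill = expired & alive & ~in_tx & still_in_pain \
            & ~(pop.phys_pdmp_compliant & other_active)
        granted = can_refill & (uu < p_refill)
        escalated = can_refill & (uu < p_refill * params.p_escalate_on_refill)
        idx = np.flatnonzero(granted)
        if idx.size:
            frac = np.where(escalated[idx],
                            np.maximum(0.0, dosing.normal(
                                params.dose_escalation_mean,
                                params.dose_escalation_sd, idx.size)),
                            0.0)
            new_dose = dose[idx] * (1.0 + frac)
            new_dose = np.where(pop.phys_cap_compliant[idx],
                                np.minimum(new_dose, params.dose_cap_mme - 1e-9),
                                new_dose)
            dose[idx] = new_dose
            lo, hi = (params.acute_len_min_days, params.acute_len_max_days) \
                if pain_type == Pain.ACUTE else \
                (params.chronic_len_min_days, params.chronic_len_max_days)
            days[idx] = dosing.integers(lo, hi + 1, size=idx.size)
            refills[idx] += 1
        lapsed = expired & ~granted
        dose[lapsed] = 0.0

    # agents whose last script lapsed and who never misused return to naive
    no_rx = (pop.rx_days_a == 0) & (pop.rx_days_c == 0)
    back = (pop.use_state == UseState.PRESCRIBED_PO) & no_rx
    pop.use_state[back] = UseState.OPIOID_NAIVE

    # --- lifetime misuse / dependence decision at first course end
    first = course_end & ~pop.first_course_done & alive
    if np.any(first):
        misuse, depend = draw_misuse_flags(pop.misuse_prop, pop.dependence_prop,
                                           u["course"])
        pop.first_course_done[first] = True
        pop.will_misuse[first] = misuse[first]
        pop.will_depend[first] = depend[first]
    start_misuse = pop.will_misuse & alive & ~in_tx & pop.first_course_done \
        & ((pop.use_state == UseState.OPIOID_NAIVE)
           | (pop.use_state == UseState.PRESCRIBED_PO))
    pop.use_state[start_misuse] = UseState.MISUSE_PO

    # --- misuse -> dependence after a sustained misuse period
    misusing = oud_active_mask(pop.use_state)
    pop.misuse_days[misusing & alive] += 1
    to_dep = (pop.use_state == UseState.MISUSE_PO) & pop.will_depend \
        & (pop.misuse_days >= params.dependence_onset_days)
    pop.use_state[to_dep] = UseState.DEPENDENT_PO

    # --- dependent agents starved of prescription supply escalate to heroin
    dep = pop.use_state == UseState.DEPENDENT_PO
    pop.shortfall_days[dep & no_rx] += 1
    pop.shortfall_days[~(dep & no_rx)] = 0
    escalate = dep & (pop.shortfall_days >= params.heroin_escalation_shortfall_days) \
        & (u["heroin_escalation"] < params.p_heroin_escalation_daily)
    pop.use_state[escalate] = UseState.HEROIN_FENTANYL


def _issue_vector(pop: Population, mask: np.ndarray, pain_type: Pain,
                  params: PrescribingParams, dosing: np.random.Generator) -> None:
    idx = np.flatnonzero(mask)
    if not idx.size:
        return
    if pain_type == Pain.ACUTE:
        mean, sd = params.acute_dose_mean, params.acute_dose_sd
        lo, hi = params.acute_len_min_days, params.acute_len_max_days
        dose_arr, days_arr = pop.rx_dose_a, pop.rx_days_a
    else:
        mean, sd = params.chronic_dose_mean, params.chronic_dose_sd
        lo, hi = params.chronic_len_min_days, params.chronic_len_max_days
        dose_arr, days_arr = pop.rx_dose_c, pop.rx_days_c
    dose = np.maximum(params.dose_floor_mme, dosing.normal(mean, sd, idx.size))
    dose = np.where(pop.phys_cap_compliant[idx],
                    np.minimum(dose, params.dose_cap_mme - 1e-9), dose)
    dose_arr[idx] = dose
    days_arr[idx] = dosing.integers(lo, hi + 1, size=idx.size)
    naive = idx[pop.use_state[idx] == UseState.OPIOID_NAIVE]
    pop.use_state[naive] = UseState.PRESCRIBED_PO
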