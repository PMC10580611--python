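"""Synthetic agent population and daily internal-state dynamics.

Each agent carries three internal state variables that govern how much
opioid (in MME/day) it seeks and consumes:

* ``desire`` — MME/day sought;
* ``tolerance`` — MME/day needed to reach satiation, 0 for an
  opioid-naive agent;
* ``satiation`` — unitless level in [0, 1] for the current day.

The update rules are deliberately the simplest forms with the right
qualitative behavior: tolerance is an exponential smoother toward the
consumed dose, satiation is the capped ratio of consumption to desire,
and desire tracks the larger of pain-driven need and tolerance, plus a
small state-dependent recreational increment for misusing and dependent
agents (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (InternalDynamicsParams, ModelParams, PopulationParams,
                     PrescribingParams, TreatmentParams)
from .states import NO_TREATMENT, Modality, Pain, UseState


@dataclass(frozen=True)
class InternalState:
    """Desire / tolerance / satiation triple for one agent."""

    desire: float = 0.0
    tolerance: float = 0.0
    satiation: float = 0.0

    def __post_init__(self) -> None:
        if self.desire < 0 or self.tolerance < 0:
            raise ValueError("desire and tolerance must be non-negative")
        if not 0.0 <= self.satiation <= 1.0:
            raise ValueError("satiation must lie in [0, 1]")


def update_internal_state(state: InternalState, consumed_mme: float,
                          dynamics: InternalDynamicsParams,
                          pain_need_mme: float = 0.0,
                          extra_mme: float = 0.0) -> InternalState:
    """One daily update of the internal state after consuming ``consumed_mme``.

    ``pain_need_mme`` is the MME needed to treat the agent's current pain
    (the desire floor); ``extra_mme`` is the recreational increment of the
    agent's use state.  With zero exposure and zero need the state (0,0,0)
    is a fixed point; under a constant daily dose the tolerance converges
    to that dose.
    """
    if consumed_mme < 0:
        raise ValueError("consumed MME must be non-negative")
    a = dynamics.alpha
    tol = (1.0 - a) * state.tolerance + a * consumed_mme
    sat = min(1.0, consumed_mme / max(state.desire, dynamics.eps))
    desire = max(pain_need_mme, dynamics.beta * tol)
    if desire > 0 or extra_mme > 0:
        desire = min(dynamics.desire_cap_mme, desire + extra_mme)
    return InternalState(desire=desire, tolerance=tol, satiation=sat)


@dataclass
class AgentState:
    """Scalar snapshot of one agent (a row of the population arrays)."""

    agent_id: int
    internal: InternalState = field(default_factory=InternalState)
    use_state: UseState = UseState.OPIOID_NAIVE
    pain: Pain = Pain.NONE
    has_bupe_rx: bool = False
    ever_bupe: bool = False
    ever_used_diverted_bupe: bool = False
    is_diverter: bool = False
    is_diverted_user: bool = False
    overdose_count: int = 0
    alive: bool = True

    def __post_init__(self) -> None:
        if self.ever_used_diverted_bupe and not self.ever_bupe:
            raise ValueError("ever_used_diverted_bupe implies ever_bupe")
        if self.overdose_count < 0:
            raise ValueError("overdose_count must be non-negative")


class Population:
    """Flat-array container for all agents of one simulation.

    The engine operates on the arrays directly; :meth:`agent` and
    :meth:`to_dataframe` provide per-agent and tabular views.
    """

    def __init__(self, n: int):
        self.n = n
        self.alive = np.ones(n, dtype=bool)
        self.use_state = np.full(n, UseState.OPIOID_NAIVE, dtype=np.int8)
        self.pain = np.full(n, Pain.NONE, dtype=np.int8)
        self.acute_days_left = np.zeros(n, dtype=np.int16)
        # internal state
        self.desire = np.zeros(n)
        self.tolerance = np.zeros(n)
        self.satiation = np.zeros(n)
        self.need_acute = np.zeros(n)
        self.need_chronic = np.zeros(n)
        # prescriptions: one acute and one chronic slot per agent
        self.rx_dose_a = np.zeros(n)
        self.rx_days_a = np.zeros(n, dtype=np.int16)
        self.rx_dose_c = np.zeros(n)
        self.rx_days_c = np.zeros(n, dtype=np.int16)
        self.rx_refills_a = np.zeros(n, dtype=np.int16)
        self.rx_refills_c = np.zeros(n, dtype=np.int16)
        # per-agent physician attributes
        self.phys_refill_acute = np.zeros(n)
        self.phys_refill_chronic = np.zeros(n)
        self.phys_cap_compliant = np.zeros(n, dtype=bool)
        self.phys_pdmp_compliant = np.zeros(n, dtype=bool)
        # lifetime misuse/dependence machinery
        self.misuse_prop = np.zeros(n)
        self.dependence_prop = np.zeros(n)
        self.first_course_done = np.zeros(n, dtype=bool)
        self.will_misuse = np.zeros(n, dtype=bool)
        self.will_depend = np.zeros(n, dtype=bool)
        self.misuse_days = np.zeros(n, dtype=np.int32)
        self.shortfall_days = np.zeros(n, dtype=np.int16)
        # treatment episode
        self.modality = np.full(n, NO_TREATMENT, dtype=np.int8)
        self.tx_days = np.zeros(n, dtype=np.int32)
        self.prev_state = np.full(n, UseState.OPIOID_NAIVE, dtype=np.int8)
        # diversion flags and stock of diverted doses
        self.ever_bupe = np.zeros(n, dtype=bool)
        self.ever_used_diverted = np.zeros(n, dtype=bool)
        self.is_diverter = np.zeros(n, dtype=bool)
        self.ever_diverter = np.zeros(n, dtype=bool)
        self.did_divert = np.zeros(n, dtype=bool)
        self.is_diverted_user = np.zeros(n, dtype=bool)
        self.degree_target = np.zeros(n, dtype=np.int16)
        self.stock = np.zeros(n, dtype=np.int32)
        self.overdose_count = np.zeros(n, dtype=np.int32)

    # -- derived views ------------------------------------------------------

    @property
    def has_bupe_rx(self) -> np.ndarray:
        return (self.use_state == UseState.IN_TREATMENT) & \
               (self.modality == Modality.BUPRENORPHINE)

    def internal(self, i: int) -> InternalState:
        return InternalState(desire=float(self.desire[i]),
                             tolerance=float(self.tolerance[i]),
                             satiation=float(self.satiation[i]))

    def agent(self, i: int) -> AgentState:
        return AgentState(
            agent_id=i,
            internal=self.internal(i),
            use_state=UseState(int(self.use_state[i])),
            pain=Pain(int(self.pain[i])),
            has_bupe_rx=bool(self.has_bupe_rx[i]),
            ever_bupe=bool(self.ever_bupe[i]),
            ever_used_diverted_bupe=bool(self.ever_used_diverted[i]),
            is_diverter=bool(self.is_diverter[i]),
            is_diverted_user=bool(self.is_diverted_user[i]),
            overdose_count=int(self.overdose_count[i]),
            alive=bool(self.alive[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per agent, suitable for CSV export."""
        return pd.DataFrame({
            "agent_id": np.arange(self.n),
            "use_state": [UseState(s).name.lower() for s in self.use_state],
            "pain": [Pain(p).name.lower() for p in self.pain],
            "desire": self.desire,
            "tolerance": self.tolerance,
            "has_bupe_rx": self.has_bupe_rx,
            "ever_bupe": self.ever_bupe,
            "alive": self.alive,
        })

    # -- vectorized internal-state update ----------------------------------

    def update_internal(self, consumed: np.ndarray, pain_need: np.ndarray,
                        extra: np.ndarray, dynamics: InternalDynamicsParams,
                        active: np.ndarray | None = None) -> None:
        """Apply the daily desire/tolerance/satiation update in place."""
        if active is None:
            active = self.alive
        a = dynamics.alpha
        tol = (1.0 - a) * self.tolerance + a * consumed
        sat = np.minimum(1.0, consumed / np.maximum(self.desire, dynamics.eps))
        desire = np.maximum(pain_need, dynamics.beta * tol)
        desire = np.minimum(dynamics.desire_cap_mme,
                            np.where((desire > 0) | (extra > 0), desire + extra,
                                     desire))
        self.tolerance[active] = tol[active]
        self.satiation[active] = sat[active]
        self.desire[active] = desire[active]


def init_population(params: PopulationParams, seed,
                    dynamics: InternalDynamicsParams | None = None,
                    prescribing: PrescribingParams | None = None,
                    treatment: TreatmentParams | None = None) -> Population:
    """Synthesize the day-0 population.

    Deterministic for a fixed ``seed`` (an int or a numpy Generator).
    Chronic pain, the initial OUD pool (split between dependent PO use and
    heroin/fentanyl use), the scaled in-treatment census, per-agent
    physician attributes, lifetime misuse/dependence propensities, and
    initial chronic prescriptions are all drawn here.
    """
    params.validate()
    prescribing = prescribing or PrescribingParams()
    treatment = treatment or TreatmentParams()
    dynamics = dynamics or InternalDynamicsParams()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = params.n_agents
    pop = Population(n)

    # chronic pain and underlying pain levels
    chronic = rng.random(n) < params.chronic_pain_prevalence
    pop.pain[chronic] = Pain.CHRONIC
    high_acute = rng.random(n) < prescribing.acute_need_high_fraction
    pop.need_acute = np.where(high_acute, prescribing.acute_need_high_mme,
                              prescribing.acute_need_low_mme)
    pop.need_chronic = np.where(
        chronic,
        np.maximum(1.0, rng.normal(prescribing.chronic_need_mean,
                                   prescribing.chronic_need_sd, n)),
        0.0)

    # physicians (one per agent; refill probabilities truncated to [0, 1])
    raw_acute = rng.normal(prescribing.p_refill_acute_mean,
                           prescribing.p_refill_acute_sd, n)
    raw_chronic = rng.normal(prescribing.p_refill_chronic_mean,
                             prescribing.p_refill_chronic_sd, n)
    clamped = int(((raw_acute < 0) | (raw_acute > 1) | (raw_chronic < 0)
                   | (raw_chronic > 1)).sum())
    if clamped:
        logging.getLogger("opioidsim").debug(
            "clamped %d physician refill probabilities to [0, 1]", clamped)
    pop.phys_refill_acute = np.clip(raw_acute, 0.0, 1.0)
    pop.phys_refill_chronic = np.clip(raw_chronic, 0.0, 1.0)
    pop.phys_cap_compliant = rng.random(n) < prescribing.p_dose_cap_compliant
    pop.phys_pdmp_compliant = rng.random(n) < prescribing.p_pdmp_compliant

    # lifetime propensities
    pop.misuse_prop = rng.uniform(prescribing.misuse_prop_low,
                                  prescribing.misuse_prop_high, n)
    pop.dependence_prop = rng.uniform(prescribing.dependence_prop_low,
                                      prescribing.dependence_prop_high, n)

    # initial OUD pool
    oud = rng.random(n) < params.initial_oud_prevalence
    heroin = oud & (rng.random(n) < params.initial_heroin_fraction)
    dep = oud & ~heroin
    pop.use_state[dep] = UseState.DEPENDENT_PO
    pop.use_state[heroin] = UseState.HEROIN_FENTANYL
    level = np.clip(rng.normal(params.initial_oud_desire_mean,
                               params.initial_oud_desire_sd, n),
                    30.0, dynamics.desire_cap_mme)
    pop.desire[oud] = level[oud]
    pop.tolerance[oud] = level[oud]
    pop.will_misuse[oud] = True
    pop.will_depend[oud] = True
    pop.first_course_done[oud] = True
    pop.misuse_days[oud] = prescribing.dependence_onset_days + 1

    # scaled in-treatment census, staggered into their episodes
    m = min(params.initial_in_treatment, n)
    candidates = np.flatnonzero(~oud)
    if m > 0 and len(candidates) > 0:
        chosen = rng.choice(candidates, size=min(m, len(candidates)),
                            replace=False)
        probs = np.asarray(treatment.modality_probs, dtype=float)
        pop.use_state[chosen] = UseState.IN_TREATMENT
        pop.modality[chosen] = rng.choice(len(probs), size=len(chosen), p=probs)
        pop.tx_days[chosen] = rng.integers(0, 180, size=len(chosen))
        prev_heroin = rng.random(len(chosen)) < params.initial_heroin_fraction
        pop.prev_state[chosen] = np.where(prev_heroin, UseState.HEROIN_FENTANYL,
                                          UseState.DEPENDENT_PO)
        pop.desire[chosen] = level[chosen]
        pop.tolerance[chosen] = level[chosen]
        pop.will_misuse[chosen] = True
        pop.will_depend[chosen] = True
        pop.first_course_done[chosen] = True
        pop.misuse_days[chosen] = prescribing.dependence_onset_days + 1
        bupe = chosen[pop.modality[chosen] == Modality.BUPRENORPHINE]
        pop.ever_bupe[bupe] = True

    # initial chronic prescriptions among chronic-pain agents still naive
    eligible = chronic & (pop.use_state == UseState.OPIOID_NAIVE)
    holders = eligible & (rng.random(n) < prescribing.p_rx_given_chronic)
    k = int(holders.sum())
    if k:
        dose = np.maximum(prescribing.dose_floor_mme,
                          rng.normal(prescribing.chronic_dose_mean,
                                     prescribing.chronic_dose_sd, k))
        capped = pop.phys_cap_compliant[holders]
        dose = np.where(capped, np.minimum(dose, prescribing.dose_cap_mme - 1e-9),
                        dose)
        pop.rx_dose_c[holders] = dose
        pop.rx_days_c[holders] = rng.integers(1, prescribing.chronic_len_max_days + 1,
                                              size=k)
        pop.use_state[holders] = UseState.PRESCRIBED_PO
        pop.desire[holders] = pop.need_chronic[holders]

    return pop


@dataclass
class SourceAvailability:
    """What an agent could consume today, used by :func:`daily_consumption`."""

    rx_mme: float = 0.0  # active prescribed MME/day (sum of active scripts)
    illicit_po_available: bool = True
    heroin_available: bool = True
    diverted_bupe_day: bool = False  # today's use is a diverted-bupe dose


def daily_consumption(agent: AgentState, sources: SourceAvailability):
    """MME consumed today and its opioid type, for one agent.

    A diverted-buprenorphine day replaces all other opioid use (0 MME of
    other opioids); prescribed agents take their prescribed dose; misusing,
    dependent, and heroin-using agents consume at their desire from illicit
    sources.  Dead agents cannot consume.
    """
    from .states import OpioidType

    if not agent.alive or agent.use_state == UseState.DEAD:
        raise RuntimeError("a dead agent cannot consume")
    if sources.diverted_bupe_day:
        return 0.0, OpioidType.DIVERTED_BUPE
    s = agent.use_state
    if s in (UseState.OPIOID_NAIVE, UseState.IN_TREATMENT, UseState.POST_TREATMENT):
        return 0.0, OpioidType.NONE
    if s == UseState.PRESCRIBED_PO:
        return float(sources.rx_mme), \
            (OpioidType.PRESCRIBED_PO if sources.rx_mme > 0 else OpioidType.NONE)
    if s in (UseState.MISUSE_PO, UseState.DEPENDENT_PO):
        if not sources.illicit_po_available:
            return float(sources.rx_mme), \
                (OpioidType.PRESCRIBED_PO if sources.rx_mme > 0 else OpioidType.NONE)
        return max(float(sources.rx_mme), agent.internal.desire), OpioidType.ILLICIT_PO
    if s == UseState.HEROIN_FENTANYL:
        if not sources.heroin_available:
            return 0.0, OpioidType.NONE
        return agent.internal.desire, OpioidType.HEROIN_FENTANYL
    raise ValueError(f"unhandled use state {s!r}")
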