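"""Parameter sets for the simulator.

Every default traces to the model's key-parameter table or to a documented
design choice (see docs/methods.md).  Units are stated per field: doses in
morphine milligram equivalents (MME) per day, rates per 100 person-years,
probabilities either per day, per year, or per event as named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional


class ConfigError(ValueError):
    """Raised for a non-finite, out-of-range, or inconsistent parameter."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


def _check_pos(value: float, name: str) -> None:
    if not value > 0:
        raise ConfigError(f"{name} must be positive, got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    if not value >= 0:
        raise ConfigError(f"{name} must be non-negative, got {value!r}")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


@dataclass
class InternalDynamicsParams:
    """Tunables of the desire / tolerance / satiation update.

    tolerance follows exponential smoothing toward the consumed dose,
    ``tol' = (1 - alpha) * tol + alpha * consumed``; satiation is the
    saturating ratio ``min(1, consumed / max(desire, eps))``; desire is
    ``max(pain_need, beta * tol') + extra(state)`` capped at
    ``desire_cap_mme``.  The state-dependent extras drive the gradual
    escalation of misusing (``extra_misuse_mme``, fixed point near 60
    MME/day) and dependent (``extra_dependent_mme``, fixed point near 120
    MME/day) agents; opioid-naive agents have no extra and stay at
    (0, 0, 0) under zero exposure.
    """

    alpha: float = 0.05  # smoothing rate per day; ~20-day tolerance memory
    beta: float = 0.95  # desire tracks tolerance at this gain
    eps: float = 1e-9  # guard for satiation when desire == 0
    extra_misuse_mme: float = 3.0  # recreational increment, misuse state
    extra_dependent_mme: float = 6.0  # recreational increment, dependent state
    desire_cap_mme: float = 150.0  # ceiling on sought MME/day

    def validate(self) -> None:
        _check_prob(self.alpha, "alpha")
        _check_nonneg(self.beta, "beta")
        _check_pos(self.eps, "eps")
        _check_nonneg(self.extra_misuse_mme, "extra_misuse_mme")
        _check_nonneg(self.extra_dependent_mme, "extra_dependent_mme")
        _check_pos(self.desire_cap_mme, "desire_cap_mme")


@dataclass
class PopulationParams:
    """Synthetic-population composition at day 0.

    ``chronic_pain_prevalence`` is the statewide 1,671,000 chronic-pain
    residents over 10.5 million.  ``initial_in_treatment_statewide`` is the
    N-SSATS census of 24,227 in OUD treatment, scaled into the agent
    population by ``scale_factor``.  ``initial_oud_prevalence`` is not
    printed in the source table; the default is derived from the stated
    flow identity (5,167 treatment entrants/year at a 25% annual seeking
    probability implies ~20,668 active misusers statewide).
    """

    n_agents: int = 10_000
    chronic_pain_prevalence: float = 1_671_000 / 10_500_000
    initial_in_treatment_statewide: float = 24_227.0
    initial_oud_prevalence: float = 5_167.0 / 0.25 / 10_500_000
    initial_heroin_fraction: float = 0.30  # share of initial OUD using heroin/fentanyl
    initial_oud_desire_mean: float = 120.0  # MME/day sought by seeded OUD agents
    initial_oud_desire_sd: float = 20.0
    scale_factor: float = 1_050.0  # 10.5e6 residents / 10,000 agents

    def validate(self) -> None:
        if self.n_agents < 1:
            raise ConfigError(f"n_agents must be >= 1, got {self.n_agents}")
        for name in ("chronic_pain_prevalence", "initial_oud_prevalence",
                     "initial_heroin_fraction"):
            value = getattr(self, name)
            if not (value == value and 0.0 <= value <= 1.0):  # NaN-safe
                raise ConfigError(f"{name} must be a finite proportion in [0, 1], "
                                  f"got {value!r}")
        _check_nonneg(self.initial_in_treatment_statewide, "initial_in_treatment_statewide")
        _check_pos(self.scale_factor, "scale_factor")
        _check_pos(self.initial_oud_desire_mean, "initial_oud_desire_mean")
        _check_pos(self.initial_oud_desire_sd, "initial_oud_desire_sd")

    @property
    def initial_in_treatment(self) -> int:
        """Initial in-treatment census scaled into the agent population."""
        return int(round(self.initial_in_treatment_statewide / self.scale_factor))


# ---------------------------------------------------------------------------
# prescribing
# ---------------------------------------------------------------------------


@dataclass
class PrescribingParams:
    """Pain onset, physician behavior, and misuse/dependence seeding."""

    # Pain and opioid use states
    p_acute_pain_12mo: float = 0.15  # annual probability of developing acute pain
    acute_pain_duration_days: int = 14  # design: length of an acute-pain episode
    p_rx_given_acute: float = 0.22  # receive an opioid at acute presentation
    p_rx_given_chronic: float = 0.30  # receive an opioid at chronic presentation
    chronic_present_interval_days: float = 90.0  # design: mean days between
    # presentations of an untreated chronic-pain agent
    acute_dose_mean: float = 30.0  # MME/day, normal
    acute_dose_sd: float = 10.0
    chronic_dose_mean: float = 50.0  # MME/day, normal
    chronic_dose_sd: float = 10.0
    dose_floor_mme: float = 1.0  # truncate non-positive normal draws
    acute_len_min_days: int = 3
    acute_len_max_days: int = 7
    chronic_len_min_days: int = 7
    chronic_len_max_days: int = 28
    # Underlying pain level (MME needed), distinct from the prescribed dose
    acute_need_low_mme: float = 6.0
    acute_need_high_mme: float = 30.0
    acute_need_high_fraction: float = 0.30
    chronic_need_mean: float = 52.0
    chronic_need_sd: float = 10.0
    # Physician and prescription behaviors (per-physician draws)
    p_refill_acute_mean: float = 0.25
    p_refill_acute_sd: float = 0.10
    p_refill_chronic_mean: float = 0.90
    p_refill_chronic_sd: float = 0.10
    dose_escalation_mean: float = 0.25  # fractional dose increase on escalation
    dose_escalation_sd: float = 0.05
    p_escalate_on_refill: float = 0.20  # design: refills that carry an increase
    p_dose_cap_compliant: float = 0.927  # physicians honoring the < 90 MME/day cap
    dose_cap_mme: float = 90.0
    p_pdmp_compliant: float = 0.775  # physicians refusing overlapping scripts
    # Misuse / dependence propensities (per-agent lifetime draws)
    misuse_prop_low: float = 0.08
    misuse_prop_high: float = 0.16
    dependence_prop_low: float = 0.02
    dependence_prop_high: float = 0.14
    dependence_onset_days: int = 90  # days of misuse before dependence begins
    # PO -> heroin/fentanyl escalation (design; see methods note)
    heroin_escalation_shortfall_days: int = 7
    p_heroin_escalation_daily: float = 0.0001

    def validate(self) -> None:
        for name in ("p_acute_pain_12mo", "p_rx_given_acute", "p_rx_given_chronic",
                     "p_refill_acute_mean", "p_refill_chronic_mean",
                     "p_escalate_on_refill", "p_dose_cap_compliant",
                     "p_pdmp_compliant", "acute_need_high_fraction",
                     "misuse_prop_low", "misuse_prop_high",
                     "dependence_prop_low", "dependence_prop_high",
                     "p_heroin_escalation_daily"):
            _check_prob(getattr(self, name), name)
        for name in ("acute_dose_mean", "acute_dose_sd", "chronic_dose_mean",
                     "chronic_dose_sd", "chronic_need_mean", "chronic_need_sd",
                     "dose_cap_mme", "dose_floor_mme",
                     "chronic_present_interval_days"):
            _check_pos(getattr(self, name), name)
        if self.misuse_prop_low > self.misuse_prop_high:
            raise ConfigError("misuse propensity range is inverted")
        if self.dependence_prop_low > self.dependence_prop_high:
            raise ConfigError("dependence propensity range is inverted")
        if self.acute_len_min_days > self.acute_len_max_days:
            raise ConfigError("acute prescription length range is inverted")
        if self.chronic_len_min_days > self.chronic_len_max_days:
            raise ConfigError("chronic prescription length range is inverted")


# ---------------------------------------------------------------------------
# treatment
# ---------------------------------------------------------------------------


@dataclass
class TreatmentParams:
    """Treatment seeking, modality mix, retention, and on-treatment risk."""

    p_seek_annual: float = 0.25  # annual seeking probability (range 0.05-0.45)
    modality_probs: tuple = (0.59, 0.38, 0.03)  # methadone, buprenorphine, naltrexone
    od_rate_methadone: float = 2.0  # per 100 person-years
    od_rate_bupe: float = 2.08  # per 100 person-years
    od_rate_naltrexone_recent: float = 3.85  # per 100 p-y within 30 days of injection
    naltrexone_recent_days: int = 30
    cess_methadone_1y: float = 0.55  # cumulative cessation by 1 year
    cess_bupe_1m: float = 0.31  # cumulative cessation by 30 days
    cess_bupe_1y: float = 0.735
    cess_naltrexone_1m: float = 0.52
    cess_naltrexone_1y: float = 0.95
    annual_entrants_statewide: float = 5_167.0  # consistency check, not a driver
    tolerance_decay_daily: float = 0.0  # optional tolerance decay while in treatment

    def validate(self) -> None:
        _check_prob(self.p_seek_annual, "p_seek_annual")
        if len(self.modality_probs) not in (3, 4):
            raise ConfigError("modality_probs must have 3 (MOUD) or 4 entries")
        for p in self.modality_probs:
            _check_prob(p, "modality_probs entry")
        if abs(sum(self.modality_probs) - 1.0) > 1e-9:
            raise ConfigError(f"modality_probs must sum to 1, got "
                              f"{sum(self.modality_probs)!r}")
        for name in ("od_rate_methadone", "od_rate_bupe", "od_rate_naltrexone_recent"):
            _check_nonneg(getattr(self, name), name)
        for name in ("cess_methadone_1y", "cess_bupe_1m", "cess_bupe_1y",
                     "cess_naltrexone_1m", "cess_naltrexone_1y",
                     "tolerance_decay_daily"):
            _check_prob(getattr(self, name), name)
        if self.cess_bupe_1y < self.cess_bupe_1m:
            raise ConfigError("buprenorphine cessation milestones out of order")
        if self.cess_naltrexone_1y < self.cess_naltrexone_1m:
            raise ConfigError("naltrexone cessation milestones out of order")


# ---------------------------------------------------------------------------
# diversion
# ---------------------------------------------------------------------------


@dataclass
class DiversionParams:
    """Supply, sourcing, and demand of diverted buprenorphine."""

    p_divert_given_rx: float = 0.50  # scenario knob: 0.50 / 0.0 / 0.95
    p_use_diverted_given_oud: float = 0.10  # scenario knob: 0.10 / 0.0 / 0.50
    p_daily_use_diverted: float = 0.15  # sensitivities raise to 0.25 / 0.50
    doses_min_per_week: int = 1
    doses_max_per_week: int = 2
    p_source_friend: float = 0.80  # friend/peer vs dealer sourcing
    p_dealer_route: float = 0.20  # diverted doses routed to the dealer pool
    dealer_max_doses: int = 3
    friend_doses: int = 1
    assortativity: float = 0.45  # ever-buprenorphine homophily in edge formation
    share_targets_min: int = 1
    share_targets_max: int = 2
    degree_target_min: int = 3  # emergent sharer connectivity: mean 5, range 3-10
    degree_target_max: int = 10
    degree_target_mean: float = 5.0
    # Sensitivity-4 opioid-naive leakage (all zero outside that sensitivity)
    naive_leak_fraction: float = 0.0
    p_naive_misuse: float = 0.01
    p_naive_fatal_od: float = 0.003

    def validate(self) -> None:
        for name in ("p_divert_given_rx", "p_use_diverted_given_oud",
                     "p_daily_use_diverted", "p_source_friend", "p_dealer_route",
                     "assortativity", "naive_leak_fraction", "p_naive_misuse",
                     "p_naive_fatal_od"):
            _check_prob(getattr(self, name), name)
        if self.doses_min_per_week > self.doses_max_per_week:
            raise ConfigError("doses per week range is inverted")
        if self.share_targets_min > self.share_targets_max:
            raise ConfigError("share-target range is inverted")
        if not (self.degree_target_min <= self.degree_target_mean
                <= self.degree_target_max):
            raise ConfigError("sharer degree target mean outside its range")
        if self.dealer_max_doses < 1:
            raise ConfigError("dealer_max_doses must be >= 1")


# ---------------------------------------------------------------------------
# overdose
# ---------------------------------------------------------------------------


@dataclass
class OverdoseHazardParams:
    """Exposure -> daily overdose probability -> fatal/non-fatal resolution.

    The dose-response follows piecewise-constant hazard ratios over the
    conventional MME risk bands (<20, 20-49, 50-99, >=100) scaled by one
    free ``base_daily_hazard``, the model's single calibrated constant (see
    docs/methods.md for the calibration protocol).
    """

    mme_band_edges: tuple = (20.0, 50.0, 100.0)
    band_hazard_ratios: tuple = (1.0, 1.44, 3.73, 8.87)
    base_daily_hazard: float = 1.045e-5  # calibrated once to status-quo totals
    heroin_od_multiplier: float = 1.7
    p_fatal_given_od: float = 0.17
    heroin_fatal_multiplier: float = 1.5
    p_naloxone_available: float = 0.276
    p_reversal_given_naloxone: float = 0.875  # range 0.75-1.0
    od_rate_diverted_bupe: float = 2.08  # per 100 p-y; sensitivity 1 doubles it
    fatal_prob_is_marginal: bool = False  # if True, 0.17 applies pre-naloxone

    def validate(self) -> None:
        edges = tuple(self.mme_band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("mme_band_edges must be strictly increasing")
        if len(self.band_hazard_ratios) != len(edges) + 1:
            raise ConfigError("need one hazard ratio per MME band")
        for r in self.band_hazard_ratios:
            _check_pos(r, "band hazard ratio")
        _check_nonneg(self.base_daily_hazard, "base_daily_hazard")
        _check_nonneg(self.od_rate_diverted_bupe, "od_rate_diverted_bupe")
        _check_pos(self.heroin_od_multiplier, "heroin_od_multiplier")
        _check_pos(self.heroin_fatal_multiplier, "heroin_fatal_multiplier")
        for name in ("p_fatal_given_od", "p_naloxone_available",
                     "p_reversal_given_naloxone"):
            _check_prob(getattr(self, name), name)


# ---------------------------------------------------------------------------
# aggregate + scenarios
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Full parameter tree for one simulation."""

    population: PopulationParams = field(default_factory=PopulationParams)
    dynamics: InternalDynamicsParams = field(default_factory=InternalDynamicsParams)
    prescribing: PrescribingParams = field(default_factory=PrescribingParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    diversion: DiversionParams = field(default_factory=DiversionParams)
    overdose: OverdoseHazardParams = field(default_factory=OverdoseHazardParams)

    def validate(self) -> None:
        for part in dataclasses.fields(self):
            getattr(self, part.name).validate()

    def copy(self) -> "ModelParams":
        return dataclasses.replace(
            self,
            **{f.name: dataclasses.replace(getattr(self, f.name))
               for f in dataclasses.fields(self)},
        )


@dataclass
class ScenarioConfig:
    """One diversion-policy scenario.

    The three named scenarios are status_quo (0.50 / 0.10), controlled_only
    (0 / 0, forcing zero diversion), and increased_diversion (0.95 / 0.50).
    ``overrides`` maps dotted parameter paths (e.g. ``overdose.base_daily_hazard``)
    to replacement values.
    """

    name: str = "status_quo"
    p_divert_given_rx: float = 0.50
    p_use_diverted_given_oud: float = 0.10
    p_daily_use_diverted: float = 0.15
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("p_divert_given_rx", "p_use_diverted_given_oud",
                     "p_daily_use_diverted"):
            _check_prob(getattr(self, name), name)
        if self.name == "controlled_only" and (
                self.p_divert_given_rx != 0.0 or self.p_use_diverted_given_oud != 0.0):
            raise ConfigError("controlled_only requires both diversion "
                              "probabilities to be exactly 0")

    def apply(self, params: ModelParams) -> ModelParams:
        params = params.copy()
        params.diversion.p_divert_given_rx = self.p_divert_given_rx
        params.diversion.p_use_diverted_given_oud = self.p_use_diverted_given_oud
        params.diversion.p_daily_use_diverted = self.p_daily_use_diverted
        for path, value in self.overrides.items():
            section, _, key = path.partition(".")
            target = getattr(params, section)
            if not hasattr(target, key):
                raise ConfigError(f"unknown override path {path!r}")
            setattr(target, key, value)
        return params


def scenario_by_name(name: str) -> ScenarioConfig:
    """Return one of the three named diversion scenarios."""
    table = {
        "status_quo": (0.50, 0.10),
        "controlled_only": (0.0, 0.0),
        "increased_diversion": (0.95, 0.50),
    }
    if name not in table:
        raise ConfigError(f"unknown scenario {name!r}; expected one of {sorted(table)}")
    divert, use = table[name]
    return ScenarioConfig(name=name, p_divert_given_rx=divert,
                          p_use_diverted_given_oud=use)


@dataclass
class SensitivityConfig:
    """One of the four sensitivity analyses (or none).

    s1 doubles the diverted-buprenorphine overdose rate (2.08 -> 4.16 per
    100 p-y); s2 and s3 raise the daily diverted-use probability to 0.25
    and 0.50; s4 leaks 3% of diverted doses to opioid-naive agents with a
    1% misuse probability and 0.3% fatality upon consumption.
    """

    id: str = "none"

    def validate(self) -> None:
        if self.id not in ("none", "s1", "s2", "s3", "s4"):
            raise ConfigError(f"unknown sensitivity {self.id!r}")

    def apply(self, params: ModelParams) -> ModelParams:
        params = params.copy()
        if self.id == "s1":
            params.overdose.od_rate_diverted_bupe = 4.16
        elif self.id == "s2":
            params.diversion.p_daily_use_diverted = 0.25
        elif self.id == "s3":
            params.diversion.p_daily_use_diverted = 0.50
        elif self.id == "s4":
            params.diversion.naive_leak_fraction = 0.03
            params.diversion.p_naive_misuse = 0.01
            params.diversion.p_naive_fatal_od = 0.003
        return params


SENSITIVITY_IDS = ("none", "s1", "s2", "s3", "s4")
SCENARIO_NAMES = ("status_quo", "controlled_only", "increased_diversion")


@dataclass
class RunConfig:
    """Monte-Carlo experiment settings."""

    n_runs: int = 100
    n_agents: int = 10_000
    years: int = 5
    base_seed: int = 0
    scale_factor: float = 1_050.0

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.n_agents < 1:
            raise ConfigError("n_agents must be >= 1")
        if self.years < 0:
            raise ConfigError("years must be >= 0")
        _check_pos(self.scale_factor, "scale_factor")

    @property
    def n_days(self) -> int:
        return 365 * self.years
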