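"""Scenario engine: daily loop, Monte-Carlo experiment, and summaries.

A run advances the whole population one day at a time in a fixed order:

1. pain onset, prescribing, refills, misuse/dependence transitions;
2. treatment cessation, seeking, and entry (with diverter role draws);
3. diverted-buprenorphine supply, demand, and network upkeep (a
   replacement day must be known before consumption);
4. consumption and the desire/tolerance/satiation update;
5. overdose occurrence and fatal/non-fatal resolution.

Runs are independently seeded from ``(base_seed, run_id)``; the random
purposes that do not depend on the diversion scenario draw identical
streams across scenarios (common random numbers), so between-scenario
contrasts are computed with far less Monte-Carlo noise than the outcome
levels themselves.  Outputs scale linearly to the reference population
(10.5 million; factor 1,050 at 10,000 agents), and summaries report the
mean and the 90% interval (5th-95th percentile across runs, linear
interpolation between order statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import RunStreams
from .diversion import (DiversionLedger, PeerNetwork, activate_sharer,
                        assign_diversion_roles, build_network,
                        maintain_sharer_ties, step_diversion)
from .overdose import rate_to_daily_prob
from .params import (ModelParams, RunConfig, ScenarioConfig, SensitivityConfig,
                     SCENARIO_NAMES, SENSITIVITY_IDS, scenario_by_name)
from .population import Population, init_population
from .prescribing import step_prescribing
from .states import (NO_TREATMENT, Modality, Pain, UseState,
                     OUD_ACTIVE_STATES, oud_active_mask)
from .treatment import step_treatment

log = logging.getLogger("opioidsim")


@dataclass
class RunResult:
    """Unscaled outcome series of one simulation run."""

    run_id: int
    n_agents: int
    years: int
    daily_overdoses: np.ndarray
    daily_fatal: np.ndarray
    ever_diverted_users: int
    sharer_degrees: list
    ledger: DiversionLedger
    stock_total: int
    od_type_counts: dict = field(default_factory=dict)

    @property
    def total_overdoses(self) -> int:
        return int(self.daily_overdoses.sum())

    @property
    def fatal_overdoses(self) -> int:
        return int(self.daily_fatal.sum())

    def cumulative_fatal(self) -> np.ndarray:
        return np.cumsum(self.daily_fatal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": np.arange(1, len(self.daily_overdoses) + 1),
            "overdoses": self.daily_overdoses,
            "fatal_overdoses": self.daily_fatal,
        })


class Simulation:
    """One seeded run of one scenario/sensitivity combination.

    With ``log_events=True`` the run additionally records one row per
    overdose event and per treatment episode (exported by
    :meth:`overdose_log` and :meth:`episode_log`).
    """

    def __init__(self, params: ModelParams, run_cfg: RunConfig, run_id: int,
                 log_events: bool = False):
        params.validate()
        run_cfg.validate()
        self.params = params
        self.run_cfg = run_cfg
        self.run_id = run_id
        self.streams = RunStreams(run_cfg.base_seed, run_id, run_cfg.n_agents)
        pop_params = params.population
        if pop_params.n_agents != run_cfg.n_agents:
            import dataclasses
            pop_params = dataclasses.replace(pop_params,
                                             n_agents=run_cfg.n_agents)
        self.pop = init_population(pop_params, self.streams.gen("init"),
                                   dynamics=params.dynamics,
                                   prescribing=params.prescribing,
                                   treatment=params.treatment)
        self.net = build_network(self.pop, params.diversion,
                                 self.streams.gen("network"))
        self.ledger = DiversionLedger()
        self.od_type_counts = {"prescribed_po": 0, "illicit_po": 0,
                               "heroin_fentanyl": 0, "moud": 0,
                               "diverted_bupe": 0, "naive_bupe": 0}
        self._init_roles()
        self._was_eligible = self.pop.alive & oud_active_mask(self.pop.use_state)
        self.log_events = log_events
        self._od_rows: list = []
        self._episode_rows: list = []
        self._day = 0

    def _init_roles(self) -> None:
        pop, div = self.pop, self.params.diversion
        roles = self.streams.gen("roles")
        bupe0 = np.flatnonzero(pop.has_bupe_rx)
        if bupe0.size and div.p_divert_given_rx > 0:
            draw = roles.random(bupe0.size) < div.p_divert_given_rx
            pop.is_diverter[bupe0[draw]] = True
            pop.ever_diverter[bupe0[draw]] = True
            for i in bupe0[draw]:
                activate_sharer(pop, self.net, int(i), div,
                                self.streams.gen("network"))
        assign_diversion_roles(pop, self.net, div, roles)

    # -- daily step ---------------------------------------------------------

    def step(self, day: int) -> tuple[int, int]:
        """Advance one day; returns (overdoses, fatal_overdoses) today."""
        pop, params = self.pop, self.params
        self._day = day
        u = self.streams.daily_uniforms()

        step_prescribing(pop, params.prescribing, u, self.streams.gen("dosing"))
        entered, exited = step_treatment(pop, params.treatment,
                                         params.diversion, u,
                                         self.streams.gen("roles"))
        if self.log_events:
            for i in np.flatnonzero(entered):
                self._episode_rows.append(
                    {"run_id": self.run_id, "agent_id": int(i),
                     "modality": Modality(int(pop.modality[i])).name.lower(),
                     "start_day": day, "end_day": -1, "reason": ""})
            for i in np.flatnonzero(exited):
                self._close_episode(int(i), day, "cessation")

        # diverted-user roles are redrawn on each eligibility transition
        eligible = pop.alive & oud_active_mask(pop.use_state)
        newly = np.flatnonzero(eligible & ~self._was_eligible)
        if newly.size:
            assign_diversion_roles(pop, self.net, params.diversion,
                                   self.streams.gen("roles"), newly)
        self._was_eligible = eligible

        bupe_day, naive_fatal = step_diversion(
            pop, self.net, self.ledger, params.diversion, u, day,
            self.streams.gen("supply"), self.streams.gen("acquire"),
            self.streams.gen("network"), self.streams.gen("naive"))

        consumed, heroin_exposed = self._consume(bupe_day)
        od, fatal = self._overdose(u, consumed, heroin_exposed, bupe_day)
        return int(od.sum()) + naive_fatal, int(fatal.sum()) + naive_fatal

    def _consume(self, bupe_day: np.ndarray):
        pop, dyn = self.pop, self.params.dynamics
        s = pop.use_state
        alive = pop.alive
        rx_total = pop.rx_dose_a * (pop.rx_days_a > 0) \
            + pop.rx_dose_c * (pop.rx_days_c > 0)
        consumed = np.zeros(pop.n)
        prescribed = alive & (s == UseState.PRESCRIBED_PO)
        consumed[prescribed] = rx_total[prescribed]
        illicit = alive & ((s == UseState.MISUSE_PO)
                           | (s == UseState.DEPENDENT_PO))
        consumed[illicit] = np.maximum(pop.desire[illicit], rx_total[illicit])
        heroin = alive & (s == UseState.HEROIN_FENTANYL)
        consumed[heroin] = pop.desire[heroin]
        consumed[bupe_day] = 0.0  # replacement day: no heroin/PO consumption

        pain_need = np.where(pop.pain == Pain.ACUTE, pop.need_acute, 0.0) \
            + np.where(pop.pain == Pain.CHRONIC, pop.need_chronic, 0.0)
        extra = np.where(s == UseState.MISUSE_PO, dyn.extra_misuse_mme, 0.0) \
            + np.where((s == UseState.DEPENDENT_PO)
                       | (s == UseState.HEROIN_FENTANYL),
                       dyn.extra_dependent_mme, 0.0)
        update = alive & (s != UseState.IN_TREATMENT) & ~bupe_day
        pop.update_internal(consumed, pain_need, extra, dyn, active=update)
        return consumed, heroin & ~bupe_day

    def _overdose(self, u: dict, consumed: np.ndarray,
                  heroin_exposed: np.ndarray, bupe_day: np.ndarray):
        pop = self.pop
        oz, tz = self.params.overdose, self.params.treatment
        alive = pop.alive
        ratios = np.asarray(oz.band_hazard_ratios)
        edges = np.asarray(oz.mme_band_edges, dtype=float)

        p = np.zeros(pop.n)
        po = alive & (consumed > 0) & ~bupe_day
        band = np.searchsorted(edges, consumed[po], side="right")
        p[po] = oz.base_daily_hazard * ratios[band]
        p[heroin_exposed] *= oz.heroin_od_multiplier

        in_tx = alive & (pop.use_state == UseState.IN_TREATMENT)
        p[in_tx & (pop.modality == Modality.METHADONE)] = \
            rate_to_daily_prob(tz.od_rate_methadone)
        p[in_tx & (pop.modality == Modality.BUPRENORPHINE)] = \
            rate_to_daily_prob(tz.od_rate_bupe)
        nal = in_tx & (pop.modality == Modality.NALTREXONE)
        recent = nal & (pop.tx_days < tz.naltrexone_recent_days)
        p[recent] = rate_to_daily_prob(tz.od_rate_naltrexone_recent)
        lapsed = nal & ~recent  # protective window over: off-treatment hazard
        if np.any(lapsed):
            band_l = np.searchsorted(edges, pop.desire[lapsed], side="right")
            h = oz.base_daily_hazard * ratios[band_l]
            h = np.where(pop.prev_state[lapsed] == UseState.HEROIN_FENTANYL,
                         h * oz.heroin_od_multiplier, h)
            p[lapsed] = h
        p[bupe_day] = rate_to_daily_prob(oz.od_rate_diverted_bupe)
        np.minimum(p, 1.0, out=p)

        od = alive & (u["overdose"] < p)
        naloxone = od & (u["naloxone"] < oz.p_naloxone_available)
        reversed_ = naloxone & (u["reversal"] < oz.p_reversal_given_naloxone)
        p_fatal = np.where(heroin_exposed,
                           min(1.0, oz.p_fatal_given_od * oz.heroin_fatal_multiplier),
                           oz.p_fatal_given_od)
        if oz.fatal_prob_is_marginal:
            fatal = od & (u["fatal"] < p_fatal)
        else:
            fatal = od & ~reversed_ & (u["fatal"] < p_fatal)
        pop.overdose_count[od] += 1
        if np.any(od):
            c = self.od_type_counts
            s = pop.use_state
            c["heroin_fentanyl"] += int((od & heroin_exposed).sum())
            c["diverted_bupe"] += int((od & bupe_day).sum())
            c["moud"] += int((od & in_tx).sum())
            c["prescribed_po"] += int((od & (s == UseState.PRESCRIBED_PO)
                                       & ~bupe_day).sum())
            c["illicit_po"] += int((od & ((s == UseState.MISUSE_PO)
                                          | (s == UseState.DEPENDENT_PO))
                                    & ~bupe_day).sum())
        if self.log_events and np.any(od):
            for i in np.flatnonzero(od):
                if bupe_day[i]:
                    otype = "diverted_bupe"
                elif heroin_exposed[i]:
                    otype = "heroin_fentanyl"
                elif in_tx[i]:
                    otype = "moud"
                elif pop.use_state[i] == UseState.PRESCRIBED_PO:
                    otype = "prescribed_po"
                else:
                    otype = "illicit_po"
                self._od_rows.append(
                    {"run_id": self.run_id, "agent_id": int(i),
                     "day": self._day, "opioid_type": otype,
                     "naloxone_available": bool(naloxone[i]),
                     "reversed": bool(reversed_[i]), "fatal": bool(fatal[i])})
        if np.any(fatal):
            idx = np.flatnonzero(fatal)
            if self.log_events:
                for i in idx:
                    if pop.use_state[i] == UseState.IN_TREATMENT:
                        self._close_episode(int(i), self._day, "death")
            pop.alive[idx] = False
            pop.use_state[idx] = UseState.DEAD
            pop.modality[idx] = NO_TREATMENT
            pop.is_diverter[idx] = False
            pop.is_diverted_user[idx] = False
            pop.rx_dose_a[idx] = 0.0
            pop.rx_days_a[idx] = 0
            pop.rx_dose_c[idx] = 0.0
            pop.rx_days_c[idx] = 0
        return od, fatal

    def _close_episode(self, agent_id: int, day: int, reason: str) -> None:
        for row in reversed(self._episode_rows):
            if row["agent_id"] == agent_id and row["end_day"] == -1:
                row["end_day"] = day
                row["reason"] = reason
                return

    def overdose_log(self) -> pd.DataFrame:
        """One row per overdose event (requires ``log_events=True``)."""
        cols = ["run_id", "agent_id", "day", "opioid_type",
                "naloxone_available", "reversed", "fatal"]
        return pd.DataFrame(self._od_rows, columns=cols)

    def episode_log(self) -> pd.DataFrame:
        """One row per treatment episode started during the run."""
        cols = ["run_id", "agent_id", "modality", "start_day", "end_day",
                "reason"]
        return pd.DataFrame(self._episode_rows, columns=cols)

    # -- full run -----------------------------------------------------------

    def run(self) -> RunResult:
        n_days = self.run_cfg.n_days
        daily_od = np.zeros(n_days, dtype=np.int32)
        daily_fatal = np.zeros(n_days, dtype=np.int32)
        for day in range(n_days):
            od, fatal = self.step(day)
            daily_od[day] = od
            daily_fatal[day] = fatal
        pop = self.pop
        sharers = np.flatnonzero(pop.did_divert & pop.alive)
        # complete the final week's tie upkeep before measuring connectivity
        maintain_sharer_ties(pop, self.net, self.params.diversion,
                             self.streams.gen("network"), sharers)
        degrees = [self.net.degree(int(i), pop.alive) for i in sharers]
        return RunResult(
            run_id=self.run_id,
            n_agents=self.run_cfg.n_agents,
            years=self.run_cfg.years,
            daily_overdoses=daily_od,
            daily_fatal=daily_fatal,
            ever_diverted_users=int(pop.ever_used_diverted.sum()),
            sharer_degrees=degrees,
            ledger=self.ledger,
            stock_total=int(pop.stock.sum()),
            od_type_counts=dict(self.od_type_counts,
                                naive_bupe=self.ledger.naive_fatal),
        )


def run_simulation(scenario: ScenarioConfig, sensitivity: SensitivityConfig,
                   run_cfg: RunConfig, run_id: int = 0,
                   base_params: ModelParams | None = None) -> RunResult:
    """Execute one seeded run of a scenario/sensitivity combination."""
    scenario.validate()
    sensitivity.validate()
    params = sensitivity.apply(scenario.apply(base_params or ModelParams()))
    log.info("run %d: scenario=%s sensitivity=%s seed=(%d,%d)", run_id,
             scenario.name, sensitivity.id, run_cfg.base_seed, run_id)
    return Simulation(params, run_cfg, run_id).run()


def run_scenario(scenario: ScenarioConfig, sensitivity: SensitivityConfig,
                 run_cfg: RunConfig,
                 base_params: ModelParams | None = None) -> list:
    """All Monte-Carlo runs of one scenario/sensitivity combination."""
    return [run_simulation(scenario, sensitivity, run_cfg, run_id, base_params)
            for run_id in range(run_cfg.n_runs)]


# ---------------------------------------------------------------------------
# summaries and comparisons
# ---------------------------------------------------------------------------


@dataclass
class MetricSummary:
    mean: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.mean <= self.ci_hi):
            raise ValueError("credible interval must bracket the mean")


@dataclass
class SummaryStats:
    """Scaled Monte-Carlo aggregate of one scenario."""

    n_runs: int
    scale_factor: float
    total_overdoses: MetricSummary
    fatal_overdoses: MetricSummary
    ever_diverted_users: MetricSummary
    mean_sharer_degree: float | None = None
    sharer_degree_range: tuple | None = None

    def to_dict(self) -> dict:
        out = {"n_runs": self.n_runs, "scale_factor": self.scale_factor}
        for name in ("total_overdoses", "fatal_overdoses", "ever_diverted_users"):
            m = getattr(self, name)
            out[name] = {"mean": m.mean, "ci_lo": m.ci_lo, "ci_hi": m.ci_hi}
        out["mean_sharer_degree"] = self.mean_sharer_degree
        out["sharer_degree_range"] = (list(self.sharer_degree_range)
                                      if self.sharer_degree_range else None)
        return out


def _summarize(values: np.ndarray, scale: float) -> MetricSummary:
    values = np.asarray(values, dtype=float) * scale
    lo, hi = np.percentile(values, [5.0, 95.0])  # linear interpolation
    mean = float(values.mean())
    return MetricSummary(mean=mean, ci_lo=min(float(lo), mean),
                         ci_hi=max(float(hi), mean))


def summarize_runs(results, scale_factor: float = 1.0) -> SummaryStats:
    """Scaled means and 90% credible intervals across Monte-Carlo runs.

    The credible interval is the 5th-95th percentile of the per-run
    (scaled) outcome, with linear interpolation between order statistics.
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_runs needs at least one RunResult")
    totals = [r.total_overdoses for r in results]
    fatals = [r.fatal_overdoses for r in results]
    users = [r.ever_diverted_users for r in results]
    degrees = [d for r in results for d in r.sharer_degrees]
    return SummaryStats(
        n_runs=len(results),
        scale_factor=scale_factor,
        total_overdoses=_summarize(totals, scale_factor),
        fatal_overdoses=_summarize(fatals, scale_factor),
        ever_diverted_users=_summarize(users, scale_factor),
        mean_sharer_degree=float(np.mean(degrees)) if degrees else None,
        sharer_degree_range=(int(min(degrees)), int(max(degrees)))
        if degrees else None,
    )


@dataclass
class ScenarioComparison:
    """Averted fatal overdoses of an alternative scenario vs a baseline.

    Positive ``averted_count`` means the alternative averts fatal
    overdoses; negative means additional fatal overdoses.
    """

    averted_count: float
    averted_pct: float | None


def compare_scenarios(baseline: SummaryStats,
                      alternative: SummaryStats) -> ScenarioComparison:
    """Averted fatal overdoses (count and percent) vs the baseline."""
    averted = baseline.fatal_overdoses.mean - alternative.fatal_overdoses.mean
    if baseline.fatal_overdoses.mean == 0:
        return ScenarioComparison(averted_count=averted, averted_pct=None)
    return ScenarioComparison(
        averted_count=averted,
        averted_pct=100.0 * averted / baseline.fatal_overdoses.mean)


def cumulative_curves(results, scale_factor: float = 1.0) -> np.ndarray:
    """Scaled mean cumulative fatal-overdose curve across runs."""
    results = list(results)
    if not results:
        raise ValueError("cumulative_curves needs at least one RunResult")
    stacked = np.stack([r.cumulative_fatal() for r in results])
    return stacked.mean(axis=0) * scale_factor


def run_experiment_grid(run_cfg: RunConfig,
                        base_params: ModelParams | None = None,
                        scenarios=SCENARIO_NAMES,
                        sensitivities=SENSITIVITY_IDS):
    """Full scenario x sensitivity grid with per-block comparisons.

    The controlled-prescription-only scenario is simulated once and its
    row reused across sensitivity blocks (the varied parameters only touch
    diverted buprenorphine, so its results are identical by construction).
    Returns ``(table, results)``: a tidy DataFrame and the raw RunResults
    keyed by ``(sensitivity, scenario)``.
    """
    base_params = base_params or ModelParams()
    results: dict = {}
    rows = []
    controlled_cache = None
    for sens_id in sensitivities:
        sens = SensitivityConfig(id=sens_id)
        summaries = {}
        for name in scenarios:
            scen = scenario_by_name(name)
            if name == "controlled_only":
                if controlled_cache is None:
                    controlled_cache = run_scenario(scen, SensitivityConfig("none"),
                                                    run_cfg, base_params)
                runs = controlled_cache
            else:
                runs = run_scenario(scen, sens, run_cfg, base_params)
            results[(sens_id, name)] = runs
            summaries[name] = summarize_runs(runs, run_cfg.scale_factor)
        baseline = summaries.get("status_quo")
        for name in scenarios:
            s = summaries[name]
            cmp_ = None
            if baseline is not None and name != "status_quo":
                cmp_ = compare_scenarios(baseline, s)
            rows.append({
                "sensitivity": sens_id,
                "scenario": name,
                "total_mean": s.total_overdoses.mean,
                "total_ci_lo": s.total_overdoses.ci_lo,
                "total_ci_hi": s.total_overdoses.ci_hi,
                "fatal_mean": s.fatal_overdoses.mean,
                "fatal_ci_lo": s.fatal_overdoses.ci_lo,
                "fatal_ci_hi": s.fatal_overdoses.ci_hi,
                "diverted_users_mean": s.ever_diverted_users.mean,
                "averted_fatal_vs_status_quo":
                    cmp_.averted_count if cmp_ else np.nan,
                "averted_pct_vs_status_quo":
                    cmp_.averted_pct if cmp_ else np.nan,
            })
    return pd.DataFrame(rows), results
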