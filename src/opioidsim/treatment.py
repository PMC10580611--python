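"""Treatment seeking, MOUD assignment, retention, and on-treatment risk.

Retention is modelled as piecewise-constant daily hazards chosen to
reproduce the published cumulative cessation milestones exactly under
exponential survival.  For buprenorphine (0.31 by 30 days, 0.735 by one
year):

    h1 = -ln(1 - 0.31) / 30          on days 1..30
    h2 = -ln((1 - 0.735)/(1 - 0.31)) / 335   on days 31.. (continuing after
                                              day 365)

Naltrexone uses the same construction (0.52 / 0.95); methadone has a
single piece, ``h = -ln(1 - 0.55) / 365``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .overdose import annual_to_daily_prob, rate_to_daily_prob
from .params import TreatmentParams
from .population import Population
from .states import (NO_TREATMENT, Modality, UseState, OUD_ACTIVE_STATES,
                     oud_active_mask)


@dataclass
class TreatmentEpisode:
    """One MOUD treatment episode."""

    modality: Modality
    start_day: int
    days_in_treatment: int = 0

    def __post_init__(self) -> None:
        if self.days_in_treatment < 0:
            raise ValueError("days_in_treatment must be non-negative")


def seek_treatment(agent, params: TreatmentParams,
                   rng: np.random.Generator) -> bool:
    """Daily treatment-seeking draw for one agent.

    Only agents actively misusing POs or using heroin/fentanyl are
    eligible; the 25% annual probability becomes
    ``1 - 0.75 ** (1/365)`` per day.
    """
    if agent.use_state not in OUD_ACTIVE_STATES:
        return False
    return bool(rng.random() < annual_to_daily_prob(params.p_seek_annual))


def assign_moud(params: TreatmentParams, rng: np.random.Generator) -> Modality:
    """Categorical modality draw (0.59 methadone / 0.38 buprenorphine /
    0.03 naltrexone by default)."""
    probs = np.asarray(params.modality_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        from .params import ConfigError
        raise ConfigError("modality probabilities must sum to 1")
    return Modality(int(rng.choice(len(probs), p=probs)))


def _two_piece_hazards(p_1m: float, p_1y: float,
                       day_break: int = 30) -> tuple[float, float]:
    h1 = -np.log1p(-p_1m) / day_break
    h2 = (-np.log1p(-p_1y) + np.log1p(-p_1m)) / (365 - day_break)
    return float(h1), float(h2)


def cessation_hazard(modality: Modality, days_in_treatment: int,
                     params: TreatmentParams | None = None) -> float:
    """Daily cessation probability at a given episode day.

    Piecewise-constant, reproducing the cumulative milestones; the late
    piece continues beyond one year.  Vector use goes through
    :func:`cessation_hazard_array`.
    """
    params = params or TreatmentParams()
    if days_in_treatment < 0:
        raise ValueError("days_in_treatment must be non-negative")
    if modality == Modality.METHADONE:
        h = -float(np.log1p(-params.cess_methadone_1y)) / 365.0
        return -float(np.expm1(-h))
    if modality == Modality.BUPRENORPHINE:
        h1, h2 = _two_piece_hazards(params.cess_bupe_1m, params.cess_bupe_1y)
    elif modality == Modality.NALTREXONE:
        h1, h2 = _two_piece_hazards(params.cess_naltrexone_1m,
                                    params.cess_naltrexone_1y)
    elif modality == Modality.NON_PHARMACOLOGIC:
        # no published milestones; treated like buprenorphine retention
        h1, h2 = _two_piece_hazards(params.cess_bupe_1m, params.cess_bupe_1y)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    h = h1 if days_in_treatment < 30 else h2
    return -float(np.expm1(-h))


def cessation_hazard_array(modality: np.ndarray, tx_days: np.ndarray,
                           params: TreatmentParams) -> np.ndarray:
    """Vectorized :func:`cessation_hazard` over modality / episode-day arrays."""
    h = np.zeros(modality.shape, dtype=float)
    h_m = -np.log1p(-params.cess_methadone_1y) / 365.0
    hb1, hb2 = _two_piece_hazards(params.cess_bupe_1m, params.cess_bupe_1y)
    hn1, hn2 = _two_piece_hazards(params.cess_naltrexone_1m,
                                  params.cess_naltrexone_1y)
    early = tx_days < 30
    h = np.where(modality == Modality.METHADONE, h_m, h)
    h = np.where((modality == Modality.BUPRENORPHINE) & early, hb1, h)
    h = np.where((modality == Modality.BUPRENORPHINE) & ~early, hb2, h)
    h = np.where((modality == Modality.NALTREXONE) & early, hn1, h)
    h = np.where((modality == Modality.NALTREXONE) & ~early, hn2, h)
    h = np.where((modality == Modality.NON_PHARMACOLOGIC) & early, hb1, h)
    h = np.where((modality == Modality.NON_PHARMACOLOGIC) & ~early, hb2, h)
    return -np.expm1(-h)  # hazard rate -> daily probability


def on_treatment_overdose_rate(episode: TreatmentEpisode,
                               params: TreatmentParams | None = None) -> float | None:
    """Overdose rate (per 100 person-years) while actively on MOUD.

    Methadone 2.0; buprenorphine 2.08; naltrexone 3.85 within 30 days of
    the injection.  Past the naltrexone window the protective rate lapses
    and the caller substitutes the agent's off-treatment hazard (returns
    ``None``).
    """
    params = params or TreatmentParams()
    if episode.modality == Modality.METHADONE:
        return params.od_rate_methadone
    if episode.modality == Modality.BUPRENORPHINE:
        return params.od_rate_bupe
    if episode.modality == Modality.NALTREXONE:
        if episode.days_in_treatment < params.naltrexone_recent_days:
            return params.od_rate_naltrexone_recent
        return None
    if episode.modality == Modality.NON_PHARMACOLOGIC:
        return None
    raise ValueError(f"unknown modality {episode.modality!r}")


def end_treatment(pop: Population, i: int,
                  params: TreatmentParams | None = None) -> None:
    """Return agent ``i`` to the most recent active use state.

    The pre-treatment internal state was frozen during the episode apart
    from the optional tolerance decay, so the agent resumes from (possibly
    attenuated) pre-treatment values.
    """
    params = params or TreatmentParams()
    if pop.modality[i] == NO_TREATMENT:
        raise RuntimeError(f"agent {i} has no active treatment episode")
    pop.use_state[i] = pop.prev_state[i]
    pop.modality[i] = NO_TREATMENT
    pop.tx_days[i] = 0
    pop.is_diverter[i] = False


# ---------------------------------------------------------------------------
# vectorized daily step
# ---------------------------------------------------------------------------


def step_treatment(pop: Population, params: TreatmentParams,
                   diversion_params, u: dict,
                   roles: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One day of cessation, seeking, and entry.

    Returns ``(entered, exited)`` boolean masks; the diversion module uses
    them to (re)draw diverter / diverted-user roles and grow the peer
    network.
    """
    alive = pop.alive
    in_tx = (pop.use_state == UseState.IN_TREATMENT) & alive

    # cessation first: ongoing episodes age by one day, then may end
    tx_idx = np.flatnonzero(in_tx)
    pop.tx_days[tx_idx] += 1
    exited = np.zeros(pop.n, dtype=bool)
    if tx_idx.size:
        h = cessation_hazard_array(pop.modality[tx_idx], pop.tx_days[tx_idx],
                                   params)
        exited[tx_idx] = u["cessation"][tx_idx] < h
    if np.any(exited):
        idx = np.flatnonzero(exited)
        pop.use_state[idx] = pop.prev_state[idx]
        pop.modality[idx] = NO_TREATMENT
        pop.tx_days[idx] = 0
        pop.is_diverter[idx] = False

    # optional tolerance decay while in treatment
    if params.tolerance_decay_daily:
        still = (pop.use_state == UseState.IN_TREATMENT) & alive
        pop.tolerance[still] *= (1.0 - params.tolerance_decay_daily)

    # seeking and entry
    p_seek = annual_to_daily_prob(params.p_seek_annual)
    eligible = alive & oud_active_mask(pop.use_state) & ~exited
    entered = eligible & (u["seek"] < p_seek)
    if np.any(entered):
        idx = np.flatnonzero(entered)
        probs = np.asarray(params.modality_probs, dtype=float)
        cum = np.cumsum(probs)
        pop.prev_state[idx] = pop.use_state[idx]
        pop.use_state[idx] = UseState.IN_TREATMENT
        pop.modality[idx] = np.searchsorted(cum, u["modality"][idx],
                                            side="right").astype(np.int8)
        pop.tx_days[idx] = 0
        # prescriptions lapse on entry; diverted-user role is suspended
        pop.rx_dose_a[idx] = 0.0
        pop.rx_days_a[idx] = 0
        pop.rx_dose_c[idx] = 0.0
        pop.rx_days_c[idx] = 0
        pop.is_diverted_user[idx] = False
        bupe = idx[pop.modality[idx] == Modality.BUPRENORPHINE]
        pop.ever_bupe[bupe] = True
        if bupe.size and diversion_params.p_divert_given_rx > 0:
            divert = roles.random(bupe.size) < diversion_params.p_divert_given_rx
            pop.is_diverter[bupe[divert]] = True
            pop.ever_diverter[bupe[divert]] = True
    return entered, exited
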