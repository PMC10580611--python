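"""Buprenorphine diversion through assortatively mixed peer networks.

Supply: agents in buprenorphine treatment who divert set aside 1-2 doses
per week; each dose goes to a diverted-using peer in their network or
(20%, mirroring the sourcing split) to a global dealer pool.  Demand:
flagged diverted users decide daily (15% by default) to use diverted
buprenorphine instead of their usual opioid; a user with no dose on hand
sources one from a peer (80%) or up to three days' doses from the dealer
pool.  A replacement day contributes zero heroin/PO consumption and
carries the prescribed-buprenorphine overdose rate.

Doses are conserved: every diverted dose is either in a user's stock, in
the dealer pool, consumed, or (under the opioid-naive sensitivity) leaked
to, consumed by, or still held by an opioid-naive agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .params import DiversionParams
from .population import Population
from .states import UseState, OUD_ACTIVE_STATES, oud_active_mask


class PeerNetwork:
    """Undirected agent graph; no self-loops, no duplicate edges.

    Kept as adjacency sets for O(1) neighbor access in the daily loop;
    :meth:`to_networkx` gives the standard graph object for analysis and
    :meth:`to_edgelist` a plain two-column export.
    """

    def __init__(self, n: int):
        self.n = n
        self.adj: list[set] = [set() for _ in range(n)]

    def add_edge(self, a: int, b: int) -> bool:
        if a == b:
            return False
        if b in self.adj[a]:
            return False
        self.adj[a].add(b)
        self.adj[b].add(a)
        return True

    def neighbors(self, i: int) -> list:
        return sorted(self.adj[i])

    def degree(self, i: int, alive: np.ndarray | None = None) -> int:
        """Degree of agent ``i``; dead partners are excluded when an
        ``alive`` mask is given (dead agents leave active degree counts)."""
        if alive is None:
            return len(self.adj[i])
        return sum(1 for j in self.adj[i] if alive[j])

    def edges(self):
        for a in range(self.n):
            for b in self.adj[a]:
                if a < b:
                    yield a, b

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def degree_dataframe(self, alive: np.ndarray | None = None):
        """Per-agent degree table (active degree when ``alive`` given)."""
        import pandas as pd

        return pd.DataFrame({
            "agent_id": np.arange(self.n),
            "degree": [self.degree(i, alive) for i in range(self.n)],
        })

    def to_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges():
                fh.write(f"{a}\t{b}\n")


@dataclass
class DiversionLedger:
    """Dose-conservation accounting for one run."""

    diverted_total: int = 0
    dealer_pool: int = 0
    consumed_by_users: int = 0
    leaked_to_naive: int = 0
    consumed_by_naive: int = 0
    held_by_naive: int = 0
    friend_sourced: int = 0
    dealer_sourced: int = 0
    naive_fatal: int = 0

    def conserved(self, stock_total: int) -> bool:
        return (self.consumed_by_users + self.dealer_pool + stock_total
                + self.consumed_by_naive + self.held_by_naive
                == self.diverted_total)


class NaiveOutcome(Enum):
    NONE = "none"
    NONFATAL_USE = "nonfatal_use"
    FATAL_OVERDOSE = "fatal_overdose"


def _pick_partner(pop: Population, net: PeerNetwork, i: int,
                  params: DiversionParams, rng: np.random.Generator):
    """Assortative partner choice: with probability ``assortativity`` the
    partner is drawn from ever-buprenorphine agents, else uniformly from
    the living population."""
    alive_idx = None
    if rng.random() < params.assortativity:
        candidates = np.flatnonzero(pop.ever_bupe & pop.alive)
    else:
        candidates = np.flatnonzero(pop.alive)
    for _ in range(8):  # rejection sampling for self/duplicate edges
        if candidates.size == 0:
            return None
        j = int(candidates[rng.integers(candidates.size)])
        cap = int(pop.degree_target[j]) or params.degree_target_max
        if j != i and j not in net.adj[i] and net.degree(j, pop.alive) < cap:
            return j
    return None


def activate_sharer(pop: Population, net: PeerNetwork, i: int,
                    params: DiversionParams, rng: np.random.Generator) -> None:
    """Give a newly flagged diverter a connectivity target and seed edges.

    Sharer connectivity targets the published statistic (mean 5 peers,
    range 3-10): each sharer draws a target degree 3 + Binomial(7, 2/7)
    and grows toward it one edge per week, starting from the minimum of 3.
    """
    if pop.degree_target[i] == 0:
        pop.degree_target[i] = params.degree_target_min + rng.binomial(
            params.degree_target_max - params.degree_target_min,
            (params.degree_target_mean - params.degree_target_min)
            / (params.degree_target_max - params.degree_target_min))
    while net.degree(i, pop.alive) < params.degree_target_min:
        j = _pick_partner(pop, net, i, params, rng)
        if j is None:
            break
        net.add_edge(i, j)


def activate_user(pop: Population, net: PeerNetwork, i: int,
                  params: DiversionParams, rng: np.random.Generator) -> None:
    """Connect a newly flagged diverted user to 1-2 peers (assortatively,
    so users tend to reach ever-buprenorphine sharers)."""
    for _ in range(int(rng.integers(params.share_targets_min,
                                    params.share_targets_max + 1))):
        j = _pick_partner(pop, net, i, params, rng)
        if j is not None:
            net.add_edge(i, j)


def maintain_sharer_ties(pop: Population, net: PeerNetwork,
                         params: DiversionParams,
                         rng: np.random.Generator,
                         ids) -> None:
    """Replace lost (dead) peers so sharers keep at least the minimum
    connectivity; called on each sharer's weekly upkeep day."""
    for i in ids:
        i = int(i)
        while net.degree(i, pop.alive) < params.degree_target_min:
            j = _pick_partner(pop, net, i, params, rng)
            if j is None:
                break
            net.add_edge(i, j)


def build_network(pop: Population, params: DiversionParams, seed,
                  net: PeerNetwork | None = None) -> PeerNetwork:
    """Seed the peer network over an initialized population.

    Edges then form incrementally during the run as agents take on
    diverter / diverted-user roles; this seeds baseline sociality among
    the initial OUD-spectrum agents.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    net = net or PeerNetwork(pop.n)
    pool = np.flatnonzero(oud_active_mask(pop.use_state)
                          | (pop.use_state == UseState.IN_TREATMENT))
    for i in pool:
        k = int(rng.integers(1, 3))
        for _ in range(k):
            j = _pick_partner(pop, net, int(i), params, rng)
            if j is not None:
                net.add_edge(int(i), j)
    return net


def assign_diversion_roles(pop: Population, net: PeerNetwork,
                           params: DiversionParams, rng: np.random.Generator,
                           candidates: np.ndarray | None = None) -> None:
    """(Re)draw the diverted-user role for eligible agents.

    Each agent in an active misuse/heroin state becomes a diverted user
    with probability ``p_use_diverted_given_oud``; the role persists until
    the next eligibility transition.  Diverter roles are drawn at
    buprenorphine-treatment entry (treatment step).
    """
    if candidates is None:
        candidates = np.flatnonzero(pop.alive & oud_active_mask(pop.use_state))
    candidates = np.asarray(candidates)
    if candidates.size == 0 or params.p_use_diverted_given_oud == 0.0:
        pop.is_diverted_user[candidates] = False
        return
    draw = rng.random(candidates.size) < params.p_use_diverted_given_oud
    pop.is_diverted_user[candidates] = draw
    for i in candidates[draw]:
        if not net.adj[int(i)]:
            activate_user(pop, net, int(i), params, rng)


def weekly_divert_supply(pop: Population, net: PeerNetwork,
                         ledger: DiversionLedger, params: DiversionParams,
                         rng: np.random.Generator, naive_rng: np.random.Generator,
                         diverter_ids: np.ndarray) -> int:
    """Move this week's diverted doses from the given diverters.

    Per dose: under the opioid-naive sensitivity a ``naive_leak_fraction``
    share is rerouted to a random opioid-naive agent (who may consume it
    immediately); otherwise 20% goes to the dealer pool and the rest to a
    random diverted-using peer, falling back to the dealer pool when no
    peer can take it.  Returns the number of fatal naive overdoses.
    """
    naive_fatal = 0
    for i in diverter_ids:
        i = int(i)
        n_doses = int(rng.integers(params.doses_min_per_week,
                                   params.doses_max_per_week + 1))
        ledger.diverted_total += n_doses
        pop.did_divert[i] = True
        user_peers = [j for j in net.neighbors(i)
                      if pop.is_diverted_user[j] and pop.alive[j]]
        for _ in range(n_doses):
            if params.naive_leak_fraction > 0 and \
                    rng.random() < params.naive_leak_fraction:
                naive_fatal += _leak_to_naive(pop, ledger, params, naive_rng)
                continue
            if rng.random() < params.p_dealer_route or not user_peers:
                ledger.dealer_pool += 1
            else:
                j = user_peers[int(rng.integers(len(user_peers)))]
                pop.stock[j] += 1
    ledger.naive_fatal += naive_fatal
    return naive_fatal


def _leak_to_naive(pop: Population, ledger: DiversionLedger,
                   params: DiversionParams, rng: np.random.Generator) -> int:
    """Route one dose to a random opioid-naive agent; resolve immediately."""
    naive = np.flatnonzero(pop.alive & (pop.use_state == UseState.OPIOID_NAIVE))
    if naive.size == 0:
        ledger.dealer_pool += 1
        return 0
    ledger.leaked_to_naive += 1
    j = int(naive[rng.integers(naive.size)])
    outcome = naive_exposure_draw(params, rng)
    if outcome == NaiveOutcome.NONE:
        ledger.held_by_naive += 1
        return 0
    ledger.consumed_by_naive += 1
    pop.ever_bupe[j] = True
    pop.ever_used_diverted[j] = True
    if outcome == NaiveOutcome.FATAL_OVERDOSE:
        pop.alive[j] = False
        pop.use_state[j] = UseState.DEAD
        pop.overdose_count[j] += 1
        return 1
    return 0


def naive_exposure_draw(params: DiversionParams,
                        rng: np.random.Generator) -> NaiveOutcome:
    """Outcome of one leaked dose reaching an opioid-naive agent.

    Consumption with probability ``p_naive_misuse`` (1%); upon
    consumption, fatal overdose with probability ``p_naive_fatal_od``
    (0.3%, the Poison-Control-derived estimate).
    """
    if rng.random() >= params.p_naive_misuse:
        return NaiveOutcome.NONE
    if rng.random() < params.p_naive_fatal_od:
        return NaiveOutcome.FATAL_OVERDOSE
    return NaiveOutcome.NONFATAL_USE


def naive_exposure(agent, params: DiversionParams,
                   rng: np.random.Generator) -> NaiveOutcome:
    """Per-agent wrapper of :func:`naive_exposure_draw`.

    Only meaningful under the opioid-naive sensitivity (a non-zero leak
    fraction); the agent must be opioid-naive.
    """
    if params.naive_leak_fraction == 0.0:
        raise RuntimeError("opioid-naive exposure requires the naive-leakage "
                           "sensitivity to be active")
    if agent.use_state != UseState.OPIOID_NAIVE:
        raise RuntimeError("only opioid-naive agents take this pathway")
    return naive_exposure_draw(params, rng)


def acquire_diverted(pop: Population, net: PeerNetwork,
                     ledger: DiversionLedger, params: DiversionParams,
                     i: int, rng: np.random.Generator) -> int:
    """Source diverted buprenorphine for user ``i`` with an empty stock.

    With probability 0.80 a single dose comes from a network peer holding
    supply; otherwise (or when no peer has any) up to 3 doses come from
    the dealer pool.  Returns the number of doses acquired (0 on failure).
    """
    friend_first = rng.random() < params.p_source_friend
    if friend_first:
        holders = [j for j in net.neighbors(i)
                   if pop.stock[j] > 0 and pop.alive[j]]
        if holders:
            j = holders[int(rng.integers(len(holders)))]
            pop.stock[j] -= 1
            pop.stock[i] += params.friend_doses
            ledger.friend_sourced += 1
            return params.friend_doses
    if ledger.dealer_pool > 0:
        want = int(rng.integers(1, params.dealer_max_doses + 1))
        got = min(want, ledger.dealer_pool)
        ledger.dealer_pool -= got
        pop.stock[i] += got
        ledger.dealer_sourced += got
        return got
    return 0


def diverted_use_decision(agent, params: DiversionParams,
                          rng: np.random.Generator) -> bool:
    """Daily decision of a flagged diverted user to use diverted
    buprenorphine instead of the usual opioid (15% by default)."""
    if not agent.is_diverted_user:
        return False
    return bool(rng.random() < params.p_daily_use_diverted)


def step_diversion(pop: Population, net: PeerNetwork, ledger: DiversionLedger,
                   params: DiversionParams, u: dict, day: int,
                   supply_rng: np.random.Generator,
                   acquire_rng: np.random.Generator,
                   network_rng: np.random.Generator,
                   naive_rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One day of diversion: weekly supply, daily demand, network upkeep.

    Returns ``(bupe_day, naive_fatal)``: the mask of agents whose opioid
    use is replaced by a diverted-buprenorphine dose today, and the count
    of fatal opioid-naive overdoses from leaked doses.
    """
    n = pop.n
    bupe_day = np.zeros(n, dtype=bool)
    naive_fatal = 0

    active_diverters = pop.is_diverter & pop.has_bupe_rx & pop.alive
    if np.any(active_diverters):
        ids = np.flatnonzero(active_diverters)
        week_mask = (day + ids) % 7 == 0
        # weekly network growth toward each sharer's connectivity target
        for i in ids[week_mask]:
            i = int(i)
            activate_sharer(pop, net, i, params, network_rng)
            if net.degree(i, pop.alive) < pop.degree_target[i]:
                j = _pick_partner(pop, net, i, params, network_rng)
                if j is not None:
                    net.add_edge(i, j)
        naive_fatal = weekly_divert_supply(pop, net, ledger, params,
                                           supply_rng, naive_rng,
                                           ids[week_mask])
    former = pop.did_divert & pop.alive & ~active_diverters
    if np.any(former):
        ids_f = np.flatnonzero(former)
        maintain_sharer_ties(pop, net, params, network_rng,
                             ids_f[(day + ids_f) % 7 == 0])

    if params.p_daily_use_diverted > 0:
        want = pop.alive & pop.is_diverted_user \
            & oud_active_mask(pop.use_state) \
            & (u["diverted_use"] < params.p_daily_use_diverted)
        for i in np.flatnonzero(want):
            i = int(i)
            if pop.stock[i] == 0:
                acquire_diverted(pop, net, ledger, params, i, acquire_rng)
            if pop.stock[i] > 0:
                pop.stock[i] -= 1
                ledger.consumed_by_users += 1
                bupe_day[i] = True
                pop.ever_used_diverted[i] = True
                pop.ever_bupe[i] = True
    return bupe_day, naive_fatal
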