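"""Named, per-purpose random streams for one simulation run.

Each run derives an independent generator per *purpose* (pain onset,
prescribing, overdose occurrence, ...) from ``SeedSequence([base_seed,
run_id, purpose_index])``.  Purposes whose draws are taken as full
population-length arrays every day stay aligned across scenarios run with
the same ``(base_seed, run_id)``; that common-random-number coupling is
what lets small between-scenario differences (a few fatal overdoses per
run) be resolved without enormous replication.
"""

from __future__ import annotations

import numpy as np

#: Purposes with one full-length uniform array drawn every simulated day,
#: in this fixed order, regardless of scenario.  Do not reorder: alignment
#: across scenarios depends on the draw schedule being identical.
ALIGNED_PURPOSES = (
    "pain", "rx_acute", "rx_chronic", "refill_acute", "refill_chronic",
    "course", "heroin_escalation", "seek", "modality", "cessation",
    "diverted_use", "overdose", "naloxone", "reversal", "fatal",
)

#: Event-driven purposes with variable-size draws (population synthesis,
#: dose sampling, diversion mechanics, network growth, role assignment).
EVENT_PURPOSES = ("init", "dosing", "roles", "supply", "acquire",
                  "network", "naive")

_ALL = ALIGNED_PURPOSES + EVENT_PURPOSES
_INDEX = {name: i for i, name in enumerate(_ALL)}


class RunStreams:
    """Bundle of named generators for one (base_seed, run_id) pair."""

    def __init__(self, base_seed: int, run_id: int, n_agents: int):
        self.n = n_agents
        self._gen = {
            name: np.random.default_rng(
                np.random.SeedSequence([int(base_seed), int(run_id), _INDEX[name]]))
            for name in _ALL
        }

    def gen(self, name: str) -> np.random.Generator:
        return self._gen[name]

    def daily_uniforms(self) -> dict:
        """One population-length uniform array per aligned purpose."""
        n = self.n
        return {name: self._gen[name].random(n, dtype=np.float32)
                for name in ALIGNED_PURPOSES}
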