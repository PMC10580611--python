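"""Enumerations shared across the simulator.

State codes are small integers so that the engine can hold the whole
population in flat numpy arrays while the public API still speaks in
named states.
"""

from __future__ import annotations

from enum import IntEnum


class UseState(IntEnum):
    """Opioid-use state of one agent.

    ``DEAD`` is absorbing: dead agents take no actions and are excluded
    from active-network degree counts.  ``IN_TREATMENT`` always carries an
    active treatment episode.  ``POST_TREATMENT`` exists for API
    completeness; the default state machine returns an agent directly to
    the most recent active use state when an episode ends.
    """

    OPIOID_NAIVE = 0
    PRESCRIBED_PO = 1
    MISUSE_PO = 2
    DEPENDENT_PO = 3
    HEROIN_FENTANYL = 4
    IN_TREATMENT = 5
    POST_TREATMENT = 6
    DEAD = 7


#: Use states eligible for treatment seeking and for the diverted-buprenorphine
#: user role: active misuse of POs or heroin/fentanyl use.
OUD_ACTIVE_STATES = (
    UseState.MISUSE_PO,
    UseState.DEPENDENT_PO,
    UseState.HEROIN_FENTANYL,
)


def oud_active_mask(use_state):
    """Boolean mask of active misuse/heroin states (vectorized)."""
    return ((use_state == UseState.MISUSE_PO)
            | (use_state == UseState.DEPENDENT_PO)
            | (use_state == UseState.HEROIN_FENTANYL))


class Pain(IntEnum):
    NONE = 0
    ACUTE = 1
    CHRONIC = 2


class Modality(IntEnum):
    """MOUD treatment modality (plus an optional non-pharmacologic branch)."""

    METHADONE = 0
    BUPRENORPHINE = 1
    NALTREXONE = 2
    NON_PHARMACOLOGIC = 3


#: Sentinel for "no active treatment episode" in the modality array.
NO_TREATMENT = -1


class OpioidType(IntEnum):
    """Opioid type consumed on a given day, used to pick the overdose hazard."""

    NONE = 0
    PRESCRIBED_PO = 1
    ILLICIT_PO = 2
    HEROIN_FENTANYL = 3
    MOUD = 4
    DIVERTED_BUPE = 5
    NAIVE_BUPE = 6
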