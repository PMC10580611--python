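"""Desire / tolerance / satiation dynamics for a single agent.

Feeds a constant 30 MME/day prescribed dose to one agent for three
months, then lets the agent misuse (small recreational increment).  The
printed rows show tolerance converging to the consumed dose and desire
escalating once misuse begins.
"""

from opioidsim import InternalState, update_internal_state
from opioidsim.params import InternalDynamicsParams

dyn = InternalDynamicsParams()
state = InternalState()

print("day  consumed  tolerance  desire  satiation")
for day in range(1, 271):
    if day <= 90:  # compliant use of a 30 MME/day prescription
        consumed, extra = 30.0, 0.0
    else:  # misuse: consume at desire with the misuse increment
        consumed, extra = state.desire, dyn.extra_misuse_mme
    state = update_internal_state(state, consumed, dyn,
                                  pain_need_mme=30.0, extra_mme=extra)
    if day % 30 == 0:
        print(f"{day:3d}  {consumed:8.1f}  {state.tolerance:9.2f}  "
              f"{state.desire:6.1f}  {state.satiation:9.2f}")

print()
print("Tolerance tracks the consumed dose with a ~20-day memory; under "
      "compliant use desire stays at the pain need (30 MME/day), and "
      "after misuse begins the recreational increment pushes desire, and "
      "hence consumption and overdose risk, steadily upward.")
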