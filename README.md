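# opioidsim

A daily-step agent-based simulator of the prescription-opioid epidemic,
built to ask one policy question: **does buprenorphine diversion increase
or decrease opioid overdoses at the population level?**  It is written
for epidemiologists and health-policy modelers who want a transparent,
fully seeded, importable re-implementation of a published
opioid-policy agent-based model, with every parameter traceable to its
source and every random draw reproducible.

## The model in brief

A synthetic population of 10,000 agents (scaled ×1,050 to a 10.5-million
state) advances one day at a time for 5 years.  Agents develop acute or
chronic pain, receive opioid prescriptions from heterogeneous
physicians, and carry three internal states — *desire* (MME/day sought),
*tolerance* (MME/day needed for satiation, an exponential smoother of
consumed dose), and *satiation* ∈ [0,1].  A lifetime propensity drawn
per agent makes 8–16% of ever-prescribed agents misuse and 2–14% develop
dependence; some dependents escalate to heroin/fentanyl.  Agents with
active OUD seek MOUD treatment (25%/yr; 59/38/3% methadone/
buprenorphine/naltrexone) with retention hazards that reproduce the
published cessation milestones exactly.

Buprenorphine patients may divert 1–2 doses/week into an assortatively
mixed peer network (sharers are connected to ~5 peers, range 3–10);
flagged users replace a day's opioid use with a diverted dose (15%
daily), which swaps that day's overdose hazard for the prescribed-
buprenorphine rate (2.08 per 100 person-years).  Diverted doses are
strictly conserved.  Overdose risk is a banded function of daily MME
(hazard ratios 1 / 1.44 / 3.73 / 8.87 over <20 / 20–49 / 50–99 / ≥100
MME/day, one calibrated base hazard), ×1.7 for heroin/fentanyl; fatality
resolves through naloxone availability (27.6%), reversal (87.5%), and
conditional fatality (0.17, ×1.5 for heroin).

Three scenarios differ only in the diversion knobs — **status quo**
(50% of prescribed divert, 10% of OUD uses diverted), **controlled
prescription only** (no diversion), **increased diversion** (95% / 50%)
— plus four sensitivity analyses (doubled diverted-bupe overdose risk;
daily use 25%; daily use 50%; 3% leakage to opioid-naive agents).
Scenarios run with common random numbers, so differences of a few fatal
overdoses per run are resolvable.  See `docs/methods.md` for the full
model description, design decisions, and limitations.

## Worked example

`examples/02_single_run.py` runs one seeded status-quo run (5,000
agents, 2 years) and prints:

```
agents: 5,000, days: 730
total overdoses:        9
fatal overdoses:        0
ever used diverted bup: 19
overdoses by exposure:  {'prescribed_po': 5, 'illicit_po': 1, 'heroin_fentanyl': 0, 'moud': 2, 'diverted_bupe': 1, 'naive_bupe': 0}
doses diverted 1013, consumed by users 968, in dealer pool 0, in stocks 45
dose conservation holds: True
sharer peer counts: mean 5.1, range 3-8
```

Counts are unscaled agent-level events: at this reduced size, ~9
overdoses over two years correspond to ~2,800/year once scaled to the
full population.  Every diverted dose is accounted for (consumed, held
in a user's stock, or in the dealer pool), and sharers sit at ~5 network
peers.  `examples/03_scenario_comparison.py` runs the three scenarios at
full agent count and prints scaled means with 90% intervals and the
averted-fatal-overdose comparison; `examples/01_*` and `examples/04_*`
demonstrate the internal-state dynamics and the retention milestones.

A thin CLI wraps the same engine:

```bash
opioidsim run --scenario status_quo --runs 10 --years 5 --seed 1 --out results/
opioidsim grid --runs 5 --out results/          # 15-row scenario x sensitivity table
opioidsim compare results/status_quo_none_summary.json results/increased_diversion_none_summary.json
opioidsim curves --scenario controlled_only --out results/
```

Parameters come from a YAML file (`--config`); `examples/parameters.yaml`
lists every default with its source annotation.

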