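# Model and methods

`opioidsim` is a daily-step, discrete-time agent-based model of
prescription-opioid use, opioid use disorder (OUD), medications for OUD
(MOUD), buprenorphine diversion through peer networks, and opioid
overdose, built to compare diversion-policy scenarios on overdose
outcomes.  The synthetic population of 10,000 agents represents a 10.5
million-resident state at a linear scale factor of 1,050; each scenario
is run for 5 years (1,825 daily steps, no leap days) across independently
seeded Monte-Carlo replicates, and outcomes are reported as scaled means
with 90% intervals (5th–95th percentile across runs, linear interpolation
between order statistics).

## Internal states and opioid use

Each agent carries three internal variables updated daily after
consumption:

* **tolerance** — MME/day needed to reach satiation; exponential
  smoothing toward the consumed dose, `tol' = (1 − α)·tol + α·consumed`
  with α = 0.05 (≈ 20-day memory).  Zero for an opioid-naive agent, and a
  constant daily dose D is its exact fixed point.
* **satiation** — `min(1, consumed / max(desire, ε))`, bounded in [0, 1].
* **desire** — MME/day sought: `max(pain_need, β·tol') + extra(state)`,
  capped at 150 MME/day, with β = 0.95.  `pain_need` is the underlying
  pain level (acute: 6 MME for 70% of agents, 30 MME for 30%; chronic:
  normal 52 ± 10 MME).  `extra` is a small recreational increment tied to
  the use state (misuse +3, dependence/heroin +6 MME/day).  These
  increments are a deliberate design choice: with β ≤ 1 and no increment,
  desire could never rise above pain need, and the misuse → dependence →
  high-dose pathway would be inert.  The resulting fixed points put
  misusers near 60 MME/day and dependent agents near 120 MME/day (the
  ≥ 100 MME risk band).

Use states are opioid-naive, prescribed PO, PO misuse, PO dependence,
heroin/fentanyl use, in treatment, and dead (absorbing).  Agents in
treatment consume no illicit opioids; a diverted-buprenorphine day
replaces all other opioid use that day (buprenorphine's blocking effect
and the risk of precipitated withdrawal motivate full replacement).

## Pain and prescribing

Acute pain arises with a 15%/12-month probability (converted to a daily
hazard as `1 − (1−p)^(1/365)`) and lasts 14 days; chronic pain is a fixed
prevalence (1,671,000 / 10.5 M ≈ 15.9%) assigned at initialization and
persistent.  Presenting patients receive an opioid with probability 22%
(acute) or 30% (chronic); untreated chronic-pain agents re-present on a
~90-day cycle.  Doses are truncated normals (30 ± 10 and 50 ± 10 MME,
floor 1 MME); course lengths are uniform on 3–7 and 7–28 days.  Each
agent has one physician with refill probabilities drawn once (acute
25% ± 10%, chronic 90% ± 10%, clamped to [0, 1]); 20% of granted refills
carry a dose escalation (normal, mean +25%).  A cap-compliant physician
(92.7%) never lets a dose reach 90 MME/day; a PDMP-compliant physician
(77.5%) refuses when the patient already holds another active
prescription (the minimal mechanism consistent with a single compliance
parameter).

Misuse and dependence are per-agent *lifetime* propensities drawn once
(uniform 8–16% and 2–14% of those ever prescribed) and resolved from one
uniform draw at the end of the agent's first prescription course, with
dependence nested inside misuse, so the marginal fractions match the
published ranges exactly.  Dependence begins after 90 days of misuse.
Dependent agents cut off from prescription supply for 7+ consecutive
days escalate to heroin/fentanyl with daily probability 1e-4 (≈ 3.6%/yr;
an early value of 2e-3 made escalation near-certain over 5 years and
inflated the heroin share of overdoses to 22%, far above what the
published fatality ratio implies — see Calibration).

## Treatment

Agents actively misusing POs or using heroin seek treatment with a 25%
annual probability (daily hazard transform); entrants are assigned
methadone / buprenorphine / naltrexone at 59 / 38 / 3%.  Retention uses
piecewise-constant daily hazards that reproduce the published cumulative
cessation milestones exactly under exponential survival (buprenorphine
0.31 by day 30 and 0.735 by day 365; naltrexone 0.52 / 0.95; methadone
0.55 by one year, single piece; the late piece continues past one year).
On cessation the agent returns to the most recent active use state with
internal state intact (an optional tolerance decay during treatment
defaults to 0).  On-treatment overdose rates are 2.0 (methadone), 2.08
(buprenorphine), and 3.85 per 100 person-years for naltrexone within 30
days of injection; past that window the protective rate lapses and the
agent's dose-based hazard applies.  The initial in-treatment census is
the scaled 24,227 (23 agents); thereafter seeking governs flow.  Note an
unresolvable tension in the source material: that census with ~5,167
entrants/year implies ~4.7-year episodes, while the cessation milestones
imply ~1 year; we follow the milestones, so the census relaxes from its
initial value toward the flow-determined level during the run.

## Diversion

Scenario knobs: the probability that a buprenorphine patient diverts
(status quo 0.50; controlled-only 0; increased diversion 0.95 — the
abstract and results table agree on 95%, an alternative 90% appears once
in the methods text and is reachable by config), the probability that an
agent with OUD is a diverted-buprenorphine user (0.10 / 0 / 0.50), and
the daily probability that a user replaces the day's opioid with
diverted buprenorphine (0.15; sensitivities raise it to 0.25 / 0.50).

Diverters set aside 1–2 doses per agent-week (weeks are offset by agent
id to avoid synchronization artifacts).  Each dose goes to a random
diverted-using network peer or, with probability 0.20 (mirroring the
80/20 friend/dealer sourcing split) or when no peer can take it, to a
single global dealer pool.  A user with no dose on hand sources one dose
from a peer holding supply (80%) or 1–3 doses from the dealer pool,
falling back to the dealer when no peer has supply.  **Doses are
conserved**: every diverted dose is in a stock, in the dealer pool,
consumed, or (sensitivity 4) leaked to / consumed by an opioid-naive
agent; this is asserted in tests.  A replacement day carries the
prescribed-buprenorphine overdose rate (2.08 per 100 p-y; doubled in
sensitivity 1).  Diverted-user roles are redrawn at each eligibility
transition; diverter roles persist for the treatment episode.  Under
sensitivity 4, 3% of diverted doses are rerouted to random opioid-naive
agents, who consume with probability 1% and, upon consumption, die with
probability 0.3% (the Poison-Control-derived figure, 84 / 27,275).

The peer network is an undirected graph grown incrementally with
assortative mixing: with probability 0.45 a new edge lands on an
ever-buprenorphine agent (ever prescribed or ever used diverted),
otherwise on a uniformly random living agent.  Each sharer draws a
connectivity target `3 + Binomial(7, 2/7)` (mean 5, range 3–10,
matching the published emergent statistic), seeds the minimum of 3 edges
at activation, and grows one edge per week toward the target; partner
selection respects the chosen cap, and dead agents leave active-degree
counts.

## Overdose

Prescription-opioid exposure at `m` MME/day has daily overdose
probability `base_daily_hazard × HR(m)` with piecewise-constant hazard
ratios (1, 1.44, 3.73, 8.87) over the conventional MME bands (< 20,
20–49, 50–99, ≥ 100).  Heroin/fentanyl multiplies the dose-band hazard
by 1.7.  Agents on MOUD use the modality rates above; a
diverted-buprenorphine day uses 2.08 per 100 p-y.  Rates per 100
person-years convert to daily probabilities as `1 − exp(−rate/36,500)`.
At most one overdose event per agent-day, drawn after consumption.

An overdose resolves sequentially: naloxone available with probability
0.276 (drawn per event); if available, reversal with probability 0.875
(reversed ⇒ non-fatal); a non-reversed overdose is fatal with
probability 0.17, times 1.5 for heroin/fentanyl (capped at 1).  Whether
the 0.17 is pre- or post-naloxone is ambiguous in the source; the
sequential reading is the default and a marginal reading
(`fatal_prob_is_marginal`) is available by config.  Fatal overdoses are
absorbing: the agent dies, leaves the network's active-degree counts,
and all roles and prescriptions are cleared.

## Daily step order and random-number design

Within a day: pain/prescribing → treatment transitions → diversion
(weekly supply, the replacement-day decision, network upkeep) →
consumption and internal-state update → overdose occurrence and
resolution.  Diversion precedes consumption because the replacement-day
decision determines what is consumed.

Every run derives one generator per random *purpose* from
`SeedSequence([base_seed, run_id, purpose])`.  Purposes that do not
depend on the diversion scenario (pain, prescribing, refills, treatment
seeking/modality/cessation, overdose occurrence and resolution) draw one
full population-length uniform array per day in a fixed order, so two
scenarios run with the same `(base_seed, run_id)` see identical streams:
common random numbers.  Because a replacement day's hazard is below the
replaced exposure's hazard and both are thresholded against the same
uniform, the coupling is monotone — the controlled-only arm's fatal
count is, run for run, at least the increased-diversion arm's — which is
what makes between-scenario differences of a few fatal overdoses per
10,000 agents resolvable at modest replication.  Runs are bit-reproducible
from `(base_seed, run_id, configs)`.

## Calibration

Two quantities are not printed in the source material:

* `initial_oud_prevalence` — set from the published stock-flow identity
  rather than tuned: 5,167 treatment entrants/year at a 25% annual
  seeking probability implies ≈ 20,700 active misusers statewide
  (0.197%); with this value the simulated entrant flow reproduces the
  published entrant count by construction.  30% of the initial OUD pool
  uses heroin/fentanyl; seeded desire/tolerance is normal 120 ± 20 MME.
* `base_daily_hazard` — the single free hazard scale, tuned **once** by a
  short grid search (12–42 runs of 10,000 agents pooled over several
  seeds) so the status-quo scenario's scaled 5-year means fall inside
  the published 90% credible intervals, then frozen at 1.045e-5 for
  every scenario and sensitivity.  At that value the status-quo run
  yields ≈ 80,900 total and ≈ 10,900 fatal overdoses (scaled), a
  fatality fraction of ≈ 0.135, with the overdose burden split ≈ 57%
  chronic/acute prescription exposure, 30% illicit PO
  misuse/dependence, 6% heroin/fentanyl, and 7% on-MOUD.

Cross-scenario contrasts are genuine predictions computed with the
frozen parameters.

## What the generator does and does not emulate

The synthetic population reproduces the published prevalences, flows,
and rate parameters, but it is a deliberately stylized epidemiology: the
population is closed (no births, aging, migration, or non-overdose
mortality); heroin/fentanyl use is under-represented relative to the
real mix of overdose deaths (the published fatality fraction of ≈ 0.132,
combined with the naloxone and conditional-fatality parameters, is only
attainable when heroin accounts for a few percent of overdoses);
fentanyl contamination exists only through the calibrated 1.7/1.5
multipliers; and pain is a two-label state without intensity dynamics.
Passing tests therefore show internal consistency with the published
parameter set and reproduction of the published status-quo totals — not
validity of any single agent's trajectory against real clinical data.

A known structural limitation matters for the sensitivity contrasts:
because diverted doses are conserved and supply is bounded by the
buprenorphine-treatment census (itself bounded by the seeking rate and
the retention milestones), the diverted-dose supply, not the daily-use
probability, limits how much opioid use diversion can replace.  The
model's averted-fatal-overdose effects are therefore about 1% of fatal
overdoses (with the published sign and ordering of the main scenarios),
smaller than the published 3.35%, and raising the daily-use probability
(sensitivities 2–3) mostly shifts *when* the capped supply is consumed
rather than how much, so the S3 contrast flattens instead of growing to
the published 5.5%.  Reproducing those magnitudes would require either
abandoning dose conservation or a severalfold larger effective
buprenorphine census than the published flows support.

## Numerical choices

Person-year and annual probabilities use exact exponential transforms
(`-expm1`-based, accurate for small rates).  Dose normals are truncated
at 1 MME; physician refill probabilities are clamped to [0, 1] (a clamp
warning is logged at debug level).  Degenerate inputs: zero years yields
empty series; a single agent with zero prevalences is opioid-naive with
internal state (0, 0, 0); modality probabilities must sum to 1 within
1e-9; milestone probabilities must be non-decreasing in horizon.
Percentiles use numpy's linear interpolation.  Uniform streams are drawn
in float32 (resolution ≈ 6e-8, two orders below the smallest daily
hazard used).  Problem sizes in the shipped tests and the acceptance
script (15–40 runs per scenario) were chosen as the replication at which
the Monte-Carlo standard error of each reported mean is comfortably
inside the published credible intervals.
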