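"""Compare the three diversion scenarios with common random numbers.

Runs a small Monte-Carlo experiment (10 runs x 10,000 agents x 5 years
takes a few minutes; sizes here are reduced) and prints scaled means,
90% intervals, and averted fatal overdoses vs the status quo.
"""

from opioidsim import (RunConfig, SensitivityConfig, compare_scenarios,
                       run_scenario, scenario_by_name, summarize_runs)

cfg = RunConfig(n_runs=6, n_agents=10_000, years=5, base_seed=3)
summaries = {}
for name in ("status_quo", "controlled_only", "increased_diversion"):
    runs = run_scenario(scenario_by_name(name), SensitivityConfig("none"),
                        cfg)
    summaries[name] = summarize_runs(runs, cfg.scale_factor)
    f = summaries[name].fatal_overdoses
    print(f"{name:20s} fatal overdoses {f.mean:9,.0f} "
          f"(90% interval {f.ci_lo:,.0f}-{f.ci_hi:,.0f})")

base = summaries["status_quo"]
for name in ("controlled_only", "increased_diversion"):
    c = compare_scenarios(base, summaries[name])
    print(f"{name:20s} vs status quo: {c.averted_count:+8,.0f} fatal "
          f"overdoses averted ({c.averted_pct:+.2f}%)")
print()
print("Scenarios share per-run random streams (common random numbers), "
      "so the small averted counts are resolvable: more diversion means "
      "slightly fewer fatal overdoses, no diversion slightly more.")
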