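# Full parameter file for opioidsim (all values shown are the defaults;
# any subset of keys may be given).  Comments give the source figure from
# the model's key-parameter table; entries marked "design" are documented
# package choices (see docs/methods.md).

population:
  n_agents: 10000                       # agents per run
  chronic_pain_prevalence: 0.15914285714285714  # 1,671,000 / 10,500,000
  initial_in_treatment_statewide: 24227.0  # N-SSATS census, scaled by 1,050
  initial_oud_prevalence: 0.0019683809523809525  # 5,167 entrants/yr / 25%/yr seek / 10.5M
  initial_heroin_fraction: 0.30         # design: heroin share of seeded OUD
  initial_oud_desire_mean: 120.0        # design: MME/day, >=100 MME risk band
  initial_oud_desire_sd: 20.0
  scale_factor: 1050.0                  # 10.5 million residents / 10,000 agents

dynamics:
  alpha: 0.05                           # design: tolerance smoothing per day
  beta: 0.95                            # design: desire gain on tolerance
  eps: 1.0e-09
  extra_misuse_mme: 3.0                 # design: recreational increment, misuse
  extra_dependent_mme: 6.0              # design: recreational increment, dependence
  desire_cap_mme: 150.0                 # design

prescribing:
  p_acute_pain_12mo: 0.15               # acute pain over 12 months: 15%
  acute_pain_duration_days: 14          # design
  p_rx_given_acute: 0.22                # receive opioid, acute presentation: 22%
  p_rx_given_chronic: 0.30              # receive opioid, chronic pain: 30%
  chronic_present_interval_days: 90.0   # design
  acute_dose_mean: 30.0                 # 30 MME (normal, 10 SD)
  acute_dose_sd: 10.0
  chronic_dose_mean: 50.0               # 50 MME (normal, 10 SD)
  chronic_dose_sd: 10.0
  dose_floor_mme: 1.0                   # design: truncate non-positive draws
  acute_len_min_days: 3                 # 7 days (3-7)
  acute_len_max_days: 7
  chronic_len_min_days: 7               # 28 days (7-28)
  chronic_len_max_days: 28
  acute_need_low_mme: 6.0               # underlying acute need: 6 MME for 70%
  acute_need_high_mme: 30.0             # ... 30 MME for 30%
  acute_need_high_fraction: 0.30
  chronic_need_mean: 52.0               # underlying chronic need 52 (10 SD)
  chronic_need_sd: 10.0
  p_refill_acute_mean: 0.25             # physician refill, acute: mean 25% SD 10%
  p_refill_acute_sd: 0.10
  p_refill_chronic_mean: 0.90           # physician refill, chronic: mean 90% SD 10%
  p_refill_chronic_sd: 0.10
  dose_escalation_mean: 0.25            # mean increase on continued pain: 25%
  dose_escalation_sd: 0.05              # design
  p_escalate_on_refill: 0.20            # design: refills carrying an increase
  p_dose_cap_compliant: 0.927           # comply with <90 MME/day cap: 92.7%
  dose_cap_mme: 90.0
  p_pdmp_compliant: 0.775               # comply with PDMP laws: 77.5% (75-80%)
  misuse_prop_low: 0.08                 # misuse among prescribed: 8-16%
  misuse_prop_high: 0.16
  dependence_prop_low: 0.02             # dependence among prescribed: 2-14%
  dependence_prop_high: 0.14
  dependence_onset_days: 90             # design
  heroin_escalation_shortfall_days: 7   # design
  p_heroin_escalation_daily: 0.0001     # design (~3.6%/yr when supply-short)

treatment:
  p_seek_annual: 0.25                   # annual seeking: 25% (5-45%)
  modality_probs: [0.59, 0.38, 0.03]    # methadone / buprenorphine / naltrexone
  od_rate_methadone: 2.0                # per 100 person-years
  od_rate_bupe: 2.08                    # per 100 person-years
  od_rate_naltrexone_recent: 3.85       # per 100 p-y, injection <1 month old
  naltrexone_recent_days: 30
  cess_methadone_1y: 0.55               # cessation 0.55 by 1 year
  cess_bupe_1m: 0.31                    # 0.31 by one month
  cess_bupe_1y: 0.735                   # 0.735 by 1 year
  cess_naltrexone_1m: 0.52
  cess_naltrexone_1y: 0.95
  annual_entrants_statewide: 5167.0     # consistency check, not a driver
  tolerance_decay_daily: 0.0            # design: optional decay in treatment

diversion:
  p_divert_given_rx: 0.50               # share/sell given prescribed: 50%
  p_use_diverted_given_oud: 0.10        # use diverted given illicit use: 10%
  p_daily_use_diverted: 0.15            # daily diverted-vs-usual choice: 15%
  doses_min_per_week: 1                 # 1-2 doses diverted per week
  doses_max_per_week: 2
  p_source_friend: 0.80                 # friend/peer vs dealer: 80%
  p_dealer_route: 0.20                  # design: mirror of the sourcing split
  dealer_max_doses: 3                   # up to 3 days' doses from a dealer
  friend_doses: 1                       # a single day's dose from a friend
  assortativity: 0.45                   # assortative mixing parameter: 45%
  share_targets_min: 1                  # share with 1-2 peers
  share_targets_max: 2
  degree_target_min: 3                  # emergent sharer peers: mean 5, 3-10
  degree_target_max: 10
  degree_target_mean: 5.0
  naive_leak_fraction: 0.0              # sensitivity 4: 0.03
  p_naive_misuse: 0.01                  # sensitivity 4: 1%
  p_naive_fatal_od: 0.003               # sensitivity 4: 0.3% (84/27,275)

overdose:
  mme_band_edges: [20.0, 50.0, 100.0]   # design: conventional MME risk bands
  band_hazard_ratios: [1.0, 1.44, 3.73, 8.87]  # design: banded dose-response
  base_daily_hazard: 1.045e-05           # calibrated once to status-quo totals
  heroin_od_multiplier: 1.7             # heroin overdose-risk multiplier
  p_fatal_given_od: 0.17                # fatal given overdose
  heroin_fatal_multiplier: 1.5          # heroin fatality multiplier
  p_naloxone_available: 0.276           # naloxone available: 27.6%
  p_reversal_given_naloxone: 0.875      # reversal given naloxone: 87.5%
  od_rate_diverted_bupe: 2.08           # per 100 p-y; sensitivity 1: 4.16
  fatal_prob_is_marginal: false         # design: 0.17 applies post-naloxone
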