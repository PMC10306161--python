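clinical:
  os_1yr:
    chemo: 0.494
    chemo_immuno: 0.692
    immuno: 0.673
    targeted: 0.86
  os_1yr_postprogression: null
  p_nextline_to_prog_3mo: 0.5
  p_prog_to_nextline_3mo: 0.48
  pfs_1yr:
    chemo: 0.173
    chemo_immuno: 0.341
    immuno: 0.279
    targeted: 0.4
gaps:
  cycle_days: 30.0
  days_per_year: 365.25
  interim_tat_reference_days: null
  interim_tat_scaling: true
  mixed_sendout_tat: high
  p_second_opinion_inhouse: 0.05
  p_second_opinion_sendout: 0.1
  singlegene_tests_per_patient: 5.0
money:
  cost_inhouse_test: 600.0
  cost_machine_acquisition: 200000.0
  cost_sendout_test: 300.0
  cost_singlegene_test: 141.0
  reimb_inhouse_test: 580.0
  retest_multiplier: 1.0
  revenue_hospital_visit: 124.0
  visits_per_cycle: 1.0
scenario_current:
  comparator_mode: sendout_ngs
  discount_rate_annual: 0.035
  frac_inhouse: 0.0
  frac_sendout: 1.0
  horizon_years: 5
  patients_per_year: 500.0
scenario_proposed:
  comparator_mode: sendout_ngs
  discount_rate_annual: 0.035
  frac_inhouse: 0.75
  frac_sendout: 0.25
  horizon_years: 5
  patients_per_year: 500.0
splits:
  p_chemo_nontargeted: 0.29
  p_chemoimmuno_nontargeted: 0.36
  p_direct_targeted: 0.73
  p_immuno_nontargeted: 0.25
  p_interim: 0.27
  p_interim_switch: 0.34
tat:
  tat_inhouse: 3.0
  tat_sendout_high: 27.8
  tat_sendout_low: 10.32
testing:
  frac_blood: 0.4
  frac_tissue: 0.6
  p_actionable_blood: 0.24
  p_actionable_tissue: 0.23
  p_fail_blood: 0.005
  p_fail_tissue: 0.012
  p_insufficient_blood: 0.003
  p_insufficient_tissue: 0.05
uncertainty:
  clinical.os_1yr.chemo:
  - 0.421
  - 0.562
  clinical.os_1yr.chemo_immuno:
  - 0.641
  - 0.738
  clinical.os_1yr.immuno:
  - 0.6057
  - 0.7403000000000001
  clinical.os_1yr.targeted:
  - 0.807
  - 0.899
  clinical.p_nextline_to_prog_3mo:
  - 0.45
  - 0.55
  clinical.p_prog_to_nextline_3mo:
  - 0.432
  - 0.528
  clinical.pfs_1yr.chemo:
  - 0.12
  - 0.235
  clinical.pfs_1yr.chemo_immuno:
  - 0.288
  - 0.395
  clinical.pfs_1yr.immuno:
  - 0.25110000000000005
  - 0.30690000000000006
  clinical.pfs_1yr.targeted:
  - 0.28
  - 0.52
  gaps.p_second_opinion_inhouse:
  - 0.045000000000000005
  - 0.05500000000000001
  gaps.p_second_opinion_sendout:
  - 0.09000000000000001
  - 0.11000000000000001
  money.cost_inhouse_test:
  - 578.0
  - 908.0
  money.cost_machine_acquisition:
  - 180000.0
  - 220000.00000000003
  money.cost_sendout_test:
  - 270.0
  - 330.0
  money.cost_singlegene_test:
  - 126.9
  - 155.10000000000002
  money.reimb_inhouse_test:
  - 522.0
  - 638.0
  money.revenue_hospital_visit:
  - 112.0
  - 136.0
  splits.p_chemo_nontargeted:
  - 0.261
  - 0.319
  splits.p_chemoimmuno_nontargeted:
  - 0.324
  - 0.396
  splits.p_immuno_nontargeted:
  - 0.225
  - 0.275
  splits.p_interim:
  - 0.24300000000000002
  - 0.29700000000000004
  splits.p_interim_switch:
  - 0.30600000000000005
  - 0.37400000000000005
  tat.tat_inhouse:
  - 2.7
  - 3.3000000000000003
  tat.tat_sendout_high:
  - 25.02
  - 30.580000000000002
  tat.tat_sendout_low:
  - 9.288
  - 11.352000000000002
  testing.frac_tissue:
  - 0.54
  - 0.66
  testing.p_actionable_blood:
  - 0.216
  - 0.264
  testing.p_actionable_tissue:
  - 0.20700000000000002
  - 0.25300000000000006
  testing.p_fail_blood:
  - 0.0045000000000000005
  - 0.0055000000000000005
  testing.p_fail_tissue:
  - 0.0108
  - 0.013200000000000002
  testing.p_insufficient_blood:
  - 0.0027
  - 0.0033000000000000004
  testing.p_insufficient_tissue:
  - 0.045000000000000005
  - 0.05500000000000001
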