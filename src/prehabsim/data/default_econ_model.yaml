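# Synthetic illustrative cost-utility model for a preoperative weight-loss
# intervention before colorectal cancer resection.
#
# The structure is the hybrid model: a 30-day postoperative decision tree
# (morbidity vs no morbidity, intervention morbidity scaled by a 20 %
# relative risk reduction) feeding a 3-state yearly Markov cohort model.
# All parameter values here are synthetic placeholders in the right order
# of magnitude for a UK surgical cohort; they are NOT estimates from any
# trial or national database, and the resulting ICER is illustrative only.
# Replace with study-specific values for a real evaluation.
decision_tree:
  p_morbidity_usual: 0.40
  relative_risk_reduction: 0.20
  intervention_cost: 450.0        # TDR products + dietetic support, GBP
  branches:
    morbidity:
      cost: 13500.0               # resection + complication management, GBP
      qaly: 0.040                 # 30-day QALYs
      state: recovery
    no_morbidity:
      cost: 9000.0
      qaly: 0.055
      state: recovery

markov:
  states: [recovery, recurrence, dead]
  death_state: dead
  transition:
    recovery:   {recovery: 0.92, recurrence: 0.05, dead: 0.03}
    recurrence: {recurrence: 0.60, dead: 0.40}
    dead:       {dead: 1.0}
  state_costs:
    recovery: 300.0
    recurrence: 15000.0
    dead: 0.0
  state_utilities:
    recovery: 0.80
    recurrence: 0.55
    dead: 0.0
  horizon: 30
  cycle_length_years: 1.0
  discount_costs: 0.035
  discount_outcomes: 0.035
  half_cycle_correction: false

psa:
  n_samples: 2000
  distributions:
    tree.p_morbidity_usual:        {family: beta,   mean: 0.40,    sd: 0.06}
    tree.relative_risk_reduction:  {family: normal, mean: 0.20,    sd: 0.12}
    tree.intervention_cost:        {family: gamma,  mean: 450.0,   sd: 90.0}
    tree.branch_costs.morbidity:   {family: gamma,  mean: 13500.0, sd: 2000.0}
    tree.branch_costs.no_morbidity: {family: gamma, mean: 9000.0,  sd: 1200.0}
    markov.state_costs.recurrence: {family: gamma,  mean: 15000.0, sd: 3000.0}
    markov.state_utilities.recovery: {family: beta, mean: 0.80,    sd: 0.05}
    markov.state_utilities.recurrence: {family: beta, mean: 0.55,  sd: 0.07}

one_way:
  tree.p_morbidity_usual: [0.30, 0.50]
  tree.relative_risk_reduction: [0.05, 0.35]
  tree.intervention_cost: [250.0, 900.0]
  tree.branch_costs.morbidity: [10000.0, 18000.0]
  markov.state_costs.recurrence: [8000.0, 25000.0]
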