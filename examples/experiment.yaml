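# Replicated simulate -> estimate -> model-first experiment.
# Run with: ttemu experiment --config examples/experiment.yaml --out scratch/exp
dgp:
  n_patients: 2000
  horizon: 28
  treatment_effect: -0.3
replicates: 5
seed: 7
methods: [sdr]
learners: [linear_additive]
v_folds: 5
designs: "ABFJ"
truth_n_mc: 50000
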