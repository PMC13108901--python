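# Small end-to-end demonstration run: generate a 20-subject constructive
# cohort, analyze consistency and error structure, fit Q-learning per
# subject, and run the RSA stage on a 10-subject synthetic MEG cohort.
# Usage: transrank run --config configs/demo.yaml --outdir demo_out
seed: 7
n_subjects: 20
agent_mix:
  constructive: 0.9
  correct_rank: 0.1
dispersion: 1.2
n_perm: 1000
run_fit: true
fit_model: qlearning
fit_restarts: 4
run_rsa: true
rsa_n_subjects: 10
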