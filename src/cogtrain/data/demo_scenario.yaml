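# Small demonstration scenario: five virtual participants with typical
# trait settings (3-sessions-per-week cadence, mild practice gains,
# occasional lapses and overlong sessions).
name: demo
n_participants: 5
seed: 7
norms_n: 100
ability_sd: 1.0
test_noise_sd: 0.3
learning_rate_mean: 0.02
learning_rate_sd: 0.01
performance_noise_sd: 0.3
gap_hours_mean: 56.0
gap_hours_sd: 12.0
overlong_prob: 0.05
lapse_prob: 0.10
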