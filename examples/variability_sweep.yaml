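# Trial-to-trial variability experiment: 50 correlated trains, 10 repeated
# trials, spike-time jitter at three widths.  Seeds are mandatory; every
# stage derives its own child seed from `seed`.
experiment: variability_sweep
seed: 5
out_dir: results/variability

n_trains: 50
trial_duration: 1.0
median_rate: 4.0      # Hz, median of the log-normal per-train rates
rate_sigma: 0.8       # log-SD of the per-train rates
ramp: true            # late-trial rate ramp (motor preparatory activity)
ramp_amplitude: 2.0

n_trials: 10
intertrial_interval: 1.0
lead_in: 1.0          # 10 x (1 s trial + 1 s interval) + 1 s lead-in = 21 s

variability_kind: jitter   # or: move
sigmas_ms: [0.0, 10.0, 100.0]

spine_density: 1.0    # spines/µm on dendrite > 25 µm from the soma
cluster_spines: 5
cluster_length: 20.0  # µm, max pairwise dendritic distance within a cluster

wcta_bins: 7
rf_estimators: 500
neighbor_k: 19
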