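# Clustered-input experiment: a single trial repeated over mappings of
# trains to spine clusters with different sizes and lengths, feeding the
# weight-change triggered averages and the random-forest regressions.
experiment: cluster_sweep
seed: 21
out_dir: results/clusters

n_trains: 100
trial_duration: 1.0
ramp: true

spine_density: 2.0    # clustered input uses a dense spine subset
cluster_configs:      # [spines_per_cluster, cluster_length µm]
  - [1, 0.0]
  - [5, 10.0]
  - [5, 40.0]
  - [10, 20.0]
  - [20, 40.0]
n_mapping_seeds: 5

wcta_bins: 7
rf_estimators: 500
neighbor_k: 19
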