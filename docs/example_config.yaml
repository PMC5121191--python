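# Benchmark configuration (defaults shown; any field may be omitted).
p: 50
n: 30
n_resamples: 100
w: 0.5
eps: 0.1
cluster_l: 5
cluster_edge_prob: 0.3
hub_l: 10
sigma_targets: [0.15, 0.19, 0.22, 0.36]
rule: or
K: 5
seed: 0
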