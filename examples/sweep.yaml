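# Replicate sweep for `glvmap run --config examples/sweep.yaml --out-dir sweep/`
# One sampled climax community per replicate; one summary row each.
S: 6              # species count (exhaustive enumeration limit is 16)
C: 0.5            # pair connectivity
sigma: 0.05       # half-normal interaction scale
P_m: 0.5          # facilitation proportion
s_value: 0.1      # self-regulation (0.1 puts interactions on the same
                  # footing as growth rates; see README)
r_range: [-1.0, 1.0]
replicates: 30
seed: 0
gamma: 20.0       # per-species arrival rate
delta: 1.0        # per-species loss rate
consortium_size: 2   # 0 disables the consortium analysis
feed: 0.1            # 0 disables the feeding analysis
fast: true           # loosened integration tolerances for sweeps
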