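# Packaged three-epoch demo scenario (see docs/methods.md for the design).
# All other parameters take their library defaults: 120x120 km at 1 km cells,
# 150 source points, kernel bandwidths 15/30 kcu, 200 generations x 5 reps.
out_dir: demo_out
seed: 1
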