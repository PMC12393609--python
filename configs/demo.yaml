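# Bundled demo: 3 + 3 synthetic larvae, 60 neurons each, 300-s traces.
# All statistical thresholds keep their published defaults.
seed: 0
n_control: 3
n_deficient: 3
neurons_per_larva: 60
duration_s: 300.0
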