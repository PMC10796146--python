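# Sparse E/I balanced network (conductance-based LIF), event-driven synapses.
[model]
zoo = "coba"

[model.params]
n_exc = 320
n_inh = 80
p = 0.05
seed = 3
mode = "event"

[run]
duration = 500.0
dt = 0.1
seed = 11

[monitors]
targets = ["spike", ["V", 10]]

[output]
dir = "out"
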