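# Layer-specific excitatory and inhibitory neuron counts of the modeled
# C2 barrel column (N_inh is distributed over PV/SOM/VIP, see
# interneuron_fractions.csv; all VIP cells are merged into L2/3).
layer,n_exc,n_inh
L2/3,1691,231
L4,1656,140
L5,1095,221
L6,1288,126
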