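# Cell-type-specific background Poisson rates (spikes/s), layer-independent,
# produced by the two-stage grid calibration against the in vivo reference
# rates (see calibration module). Calibrated separately for the static-synapse
# (base) and STP (base_stp) model versions.
variant,Exc,PV,SOM,VIP
base,4400,7000,2500,3300
base_stp,4400,7000,2500,3300
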