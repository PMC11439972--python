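# Relative quantities f_PV, f_SOM, f_VIP per layer used to apportion N_inh.
# Approximate: the original fractions were digitized from an external figure;
# the values here are the per-layer interneuron counts themselves (pre-merge),
# which reproduce the documented population table exactly. Overridable.
layer,f_pv,f_som,f_vip
L2/3,90,74,67
L4,85,48,7
L5,109,105,7
L6,56,66,4
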