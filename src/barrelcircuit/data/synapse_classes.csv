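# Synapse classes: PSP amplitude definitions (mean +/- SD in mV, magnitudes;
# sign applied per class), PSC decay time constants, and delay statistics.
# background has fixed weight (SD 0) and fixed 0.1 ms delay.
name,sign,psp_mean_mv,psp_sd_mv,tau_syn_ms,delay_mean_ms,delay_sd_ms
intracortical_exc,1,0.5,0.5,2.0,1.36,0.51
intracortical_inh,-1,2.0,2.0,4.0,1.43,1.09
thalamic,1,0.49,0.13,2.0,1.72,0.73
thalamic_som,1,0.245,0.065,2.0,1.72,0.73
background,1,0.5,0.0,2.0,0.1,0.0
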