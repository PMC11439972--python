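# Asynchronous-irregular state criteria (in vivo): bounds on mean pairwise
# spike-count correlation and CV ISI. Approximate, figure-derived stand-ins
# for the published compilation; used only for flagged pass/fail reporting,
# never as exact test anchors.
metric,awake_min,awake_max,anesth_up
correlation,0.001,0.03,
cv_isi,0.9,1.5,0.6
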