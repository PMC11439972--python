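# Log-normal time-course parameters of the transient thalamic (VPM) rate
# profile r(t) = A * exp(-(ln(t-t0)-mu)^2 / (2 sigma^2)) / (t-t0) for t > t0,
# in spikes/s with t in ms after stimulus onset. Approximate, figure-derived:
# the published curve was fitted to digitized in vivo touch responses; these
# parameters emulate its shape (sharp onset a few ms after touch, peak of a
# few tens of spikes/s, decay within ~50 ms) and are overridable.
param,value
amplitude,213.0
t0_ms,1.0
mu,1.609
sigma,0.7
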