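# Connection probabilities P in percent, keyed by (source, target)
# population. Approximate, figure-derived transcription: intra-layer anchors
# printed in the text (L2/3 SOM->PV 11.81, L4 SOM->PV 36.30, L4 SOM->Exc 19.8)
# are exact; other entries are best-effort estimates in the style of the
# source data (paired recordings, morphology-based estimates, assumptions).
# Entries governed by fill-in rules (L4/L5 Exc->PV reciprocity, L5 SOM-related
# averages of L2/3 and L4, L6 copies of L5) are intentionally absent and are
# produced by the matrix assembler. range_x/range_y give the lateral sampling
# footprint (um) over which the probability applies; the model footprint
# (200x300) means no spatial rescaling is performed.
source,target,p_percent,provenance,range_x_um,range_y_um
L2/3 Exc,L2/3 Exc,9.4,paired-recording,100,100
L2/3 Exc,L2/3 PV,48.0,paired-recording,100,100
L2/3 Exc,L2/3 SOM,18.0,paired-recording,100,100
L2/3 Exc,L2/3 VIP,10.0,assumption,200,300
L2/3 PV,L2/3 Exc,43.0,paired-recording,100,100
L2/3 PV,L2/3 PV,38.0,paired-recording,100,100
L2/3 PV,L2/3 SOM,10.0,paired-recording,100,100
L2/3 PV,L2/3 VIP,12.0,assumption,200,300
L2/3 SOM,L2/3 Exc,28.0,paired-recording,100,100
L2/3 SOM,L2/3 PV,11.81,paired-recording,200,300
L2/3 SOM,L2/3 SOM,4.0,paired-recording,100,100
L2/3 SOM,L2/3 VIP,25.0,paired-recording,100,100
L2/3 VIP,L2/3 Exc,1.0,assumption,200,300
L2/3 VIP,L2/3 PV,2.0,assumption,200,300
L2/3 VIP,L2/3 SOM,32.0,paired-recording,100,100
L2/3 VIP,L2/3 VIP,3.0,assumption,200,300
L4 Exc,L4 Exc,24.3,paired-recording,100,100
L4 Exc,L4 SOM,13.0,paired-recording,100,100
L4 PV,L4 Exc,43.0,paired-recording,100,100
L4 PV,L4 PV,45.0,paired-recording,100,100
L4 PV,L4 SOM,43.0,paired-recording,100,100
L4 SOM,L4 Exc,19.8,paired-recording,200,300
L4 SOM,L4 PV,36.3,paired-recording,200,300
L4 SOM,L4 SOM,2.0,assumption,200,300
L5 Exc,L5 Exc,19.1,paired-recording,100,100
L5 PV,L5 Exc,38.0,paired-recording,100,100
L5 PV,L5 PV,50.0,paired-recording,100,100
L5 PV,L5 SOM,20.0,assumption,200,300
L5 SOM,L5 PV,30.0,paired-recording,100,100
L6 Exc,L6 Exc,2.8,paired-recording,100,100
L4 Exc,L2/3 Exc,13.0,paired-recording,100,100
L2/3 Exc,L5 Exc,9.0,paired-recording,100,100
L4 Exc,L5 Exc,5.0,morphology-estimate,200,300
L5 Exc,L2/3 Exc,2.0,morphology-estimate,200,300
L5 Exc,L6 Exc,3.0,morphology-estimate,200,300
L2/3 Exc,L4 Exc,1.5,morphology-estimate,200,300
L2/3 Exc,L6 Exc,1.0,morphology-estimate,200,300
L4 Exc,L6 Exc,1.0,morphology-estimate,200,300
L5 Exc,L4 Exc,1.0,morphology-estimate,200,300
L6 Exc,L5 Exc,2.0,morphology-estimate,200,300
L6 Exc,L4 Exc,0.5,morphology-estimate,200,300
L6 Exc,L2/3 Exc,0.2,morphology-estimate,200,300
L4 Exc,L2/3 PV,6.0,morphology-estimate,200,300
L4 Exc,L2/3 SOM,4.0,morphology-estimate,200,300
L4 Exc,L2/3 VIP,2.0,morphology-estimate,200,300
L2/3 Exc,L5 PV,4.0,morphology-estimate,200,300
L2/3 Exc,L5 SOM,3.0,morphology-estimate,200,300
L4 Exc,L5 PV,2.0,morphology-estimate,200,300
L4 Exc,L5 SOM,1.5,morphology-estimate,200,300
L5 Exc,L6 PV,2.0,morphology-estimate,200,300
L5 Exc,L6 SOM,1.5,morphology-estimate,200,300
L5 Exc,L2/3 PV,1.0,morphology-estimate,200,300
L5 Exc,L2/3 SOM,0.5,morphology-estimate,200,300
L5 Exc,L2/3 VIP,0.5,morphology-estimate,200,300
L2/3 Exc,L4 PV,1.5,morphology-estimate,200,300
L2/3 Exc,L4 SOM,1.0,morphology-estimate,200,300
L6 Exc,L5 PV,1.0,morphology-estimate,200,300
L6 Exc,L5 SOM,0.5,morphology-estimate,200,300
L5 Exc,L4 PV,0.5,morphology-estimate,200,300
L6 Exc,L4 PV,0.3,morphology-estimate,200,300
L2/3 PV,L4 Exc,1.0,morphology-estimate,200,300
L2/3 PV,L4 PV,0.8,morphology-estimate,200,300
L2/3 SOM,L4 Exc,1.5,morphology-estimate,200,300
L2/3 SOM,L4 SOM,0.5,morphology-estimate,200,300
L2/3 SOM,L5 Exc,0.5,morphology-estimate,200,300
L4 PV,L2/3 Exc,1.0,morphology-estimate,200,300
L4 PV,L2/3 PV,0.8,morphology-estimate,200,300
L4 SOM,L2/3 Exc,1.5,morphology-estimate,200,300
L4 SOM,L2/3 SOM,0.5,morphology-estimate,200,300
L5 PV,L6 Exc,1.0,morphology-estimate,200,300
L5 PV,L4 Exc,0.5,morphology-estimate,200,300
L5 SOM,L6 Exc,1.0,morphology-estimate,200,300
L5 SOM,L2/3 Exc,0.3,morphology-estimate,200,300
L6 PV,L5 Exc,0.8,morphology-estimate,200,300
L6 SOM,L5 Exc,0.8,morphology-estimate,200,300
L2/3 VIP,L4 SOM,3.0,morphology-estimate,200,300
L2/3 VIP,L5 SOM,2.0,morphology-estimate,200,300
L2/3 Exc,L6 PV,0.0,assumption,200,300
L2/3 Exc,L6 SOM,0.0,assumption,200,300
L2/3 PV,L4 SOM,0.0,assumption,200,300
L2/3 PV,L5 Exc,0.0,assumption,200,300
L2/3 PV,L5 PV,0.0,assumption,200,300
L2/3 PV,L5 SOM,0.0,assumption,200,300
L2/3 PV,L6 Exc,0.0,assumption,200,300
L2/3 PV,L6 PV,0.0,assumption,200,300
L2/3 PV,L6 SOM,0.0,assumption,200,300
L2/3 SOM,L4 PV,0.0,assumption,200,300
L2/3 SOM,L5 PV,0.0,assumption,200,300
L2/3 SOM,L5 SOM,0.0,assumption,200,300
L2/3 SOM,L6 Exc,0.0,assumption,200,300
L2/3 SOM,L6 PV,0.0,assumption,200,300
L2/3 SOM,L6 SOM,0.0,assumption,200,300
L2/3 VIP,L4 Exc,0.0,assumption,200,300
L2/3 VIP,L4 PV,0.0,assumption,200,300
L2/3 VIP,L5 Exc,0.0,assumption,200,300
L2/3 VIP,L5 PV,0.0,assumption,200,300
L2/3 VIP,L6 Exc,0.0,assumption,200,300
L2/3 VIP,L6 PV,0.0,assumption,200,300
L2/3 VIP,L6 SOM,0.0,assumption,200,300
L4 Exc,L6 PV,0.0,assumption,200,300
L4 Exc,L6 SOM,0.0,assumption,200,300
L4 PV,L2/3 SOM,0.0,assumption,200,300
L4 PV,L2/3 VIP,0.0,assumption,200,300
L4 PV,L5 Exc,0.0,assumption,200,300
L4 PV,L5 PV,0.0,assumption,200,300
L4 PV,L5 SOM,0.0,assumption,200,300
L4 PV,L6 Exc,0.0,assumption,200,300
L4 PV,L6 PV,0.0,assumption,200,300
L4 PV,L6 SOM,0.0,assumption,200,300
L4 SOM,L2/3 PV,0.0,assumption,200,300
L4 SOM,L2/3 VIP,0.0,assumption,200,300
L4 SOM,L5 Exc,0.0,assumption,200,300
L4 SOM,L5 PV,0.0,assumption,200,300
L4 SOM,L5 SOM,0.0,assumption,200,300
L4 SOM,L6 Exc,0.0,assumption,200,300
L4 SOM,L6 PV,0.0,assumption,200,300
L4 SOM,L6 SOM,0.0,assumption,200,300
L5 Exc,L4 SOM,0.0,assumption,200,300
L5 PV,L2/3 Exc,0.0,assumption,200,300
L5 PV,L2/3 PV,0.0,assumption,200,300
L5 PV,L2/3 SOM,0.0,assumption,200,300
L5 PV,L2/3 VIP,0.0,assumption,200,300
L5 PV,L4 PV,0.0,assumption,200,300
L5 PV,L4 SOM,0.0,assumption,200,300
L5 PV,L6 PV,0.0,assumption,200,300
L5 PV,L6 SOM,0.0,assumption,200,300
L5 SOM,L2/3 PV,0.0,assumption,200,300
L5 SOM,L2/3 SOM,0.0,assumption,200,300
L5 SOM,L2/3 VIP,0.0,assumption,200,300
L5 SOM,L4 Exc,0.0,assumption,200,300
L5 SOM,L4 PV,0.0,assumption,200,300
L5 SOM,L4 SOM,0.0,assumption,200,300
L5 SOM,L6 PV,0.0,assumption,200,300
L5 SOM,L6 SOM,0.0,assumption,200,300
L6 Exc,L2/3 PV,0.0,assumption,200,300
L6 Exc,L2/3 SOM,0.0,assumption,200,300
L6 Exc,L2/3 VIP,0.0,assumption,200,300
L6 Exc,L4 SOM,0.0,assumption,200,300
L6 PV,L2/3 Exc,0.0,assumption,200,300
L6 PV,L2/3 PV,0.0,assumption,200,300
L6 PV,L2/3 SOM,0.0,assumption,200,300
L6 PV,L2/3 VIP,0.0,assumption,200,300
L6 PV,L4 Exc,0.0,assumption,200,300
L6 PV,L4 PV,0.0,assumption,200,300
L6 PV,L4 SOM,0.0,assumption,200,300
L6 PV,L5 PV,0.0,assumption,200,300
L6 PV,L5 SOM,0.0,assumption,200,300
L6 SOM,L2/3 Exc,0.0,assumption,200,300
L6 SOM,L2/3 PV,0.0,assumption,200,300
L6 SOM,L2/3 SOM,0.0,assumption,200,300
L6 SOM,L2/3 VIP,0.0,assumption,200,300
L6 SOM,L4 Exc,0.0,assumption,200,300
L6 SOM,L4 PV,0.0,assumption,200,300
L6 SOM,L4 SOM,0.0,assumption,200,300
L6 SOM,L5 PV,0.0,assumption,200,300
L6 SOM,L5 SOM,0.0,assumption,200,300
TH,L4 Exc,43.0,paired-recording,200,300
TH,L4 PV,50.0,paired-recording,200,300
TH,L4 SOM,21.5,assumption,200,300
TH,L2/3 Exc,8.6,assumption,200,300
TH,L2/3 PV,10.0,assumption,200,300
TH,L5 Exc,15.0,paired-recording,200,300
TH,L5 PV,15.0,paired-recording,200,300
TH,L6 Exc,10.0,paired-recording,200,300
TH,L6 PV,10.0,paired-recording,200,300
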