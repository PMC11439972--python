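# Best-fit Tsodyks parameters per projection class. Approximate,
# figure-derived transcription: the published best-fit matrix is a figure, so
# the values here are plausible on-grid stand-ins (U on the 0.05 grid, F and D
# on the 20 ms grid) reproducing the qualitative pattern: depressing Exc->Exc
# and PV-related synapses, facilitating Exc->SOM, depressing PV->SOM,
# depressing thalamic->PV, facilitating thalamic->SOM; thalamic->Exc reuses
# the L4 Exc -> L2/3 Exc feedforward parameters. Projections not listed stay
# static (VIP-related data were excluded from the source fits). Wildcard '*'
# matches any layer; specific (source_layer, target_layer) rows win.
source_type,target_type,source_layer,target_layer,U,F_ms,D_ms
Exc,Exc,L2/3,L2/3,0.45,20,280
Exc,Exc,L4,L4,0.60,0,320
Exc,Exc,L4,L2/3,0.55,0,300
Exc,Exc,L5,L5,0.50,0,260
Exc,Exc,L6,L6,0.50,0,260
Exc,Exc,L5,L6,0.50,0,280
Exc,Exc,*,*,0.50,0,280
Exc,PV,*,*,0.75,0,500
Exc,SOM,*,*,0.10,480,60
PV,Exc,*,*,0.60,0,400
PV,PV,*,*,0.60,0,300
PV,SOM,*,*,0.55,0,400
SOM,Exc,*,*,0.45,40,240
SOM,PV,*,*,0.45,20,200
TH,PV,*,*,0.80,0,400
TH,SOM,*,*,0.10,400,100
TH,Exc,*,*,0.55,0,300
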