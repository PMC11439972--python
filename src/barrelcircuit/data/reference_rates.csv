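# In vivo reference firing rates (non-whisking state), mean +/- SD, median,
# quartiles, cell count. calibration_target marks the seven population means
# used as the background-rate optimization objective (L2/3 and L4 only).
layer,cell_type,mean,sd,median,q25,q75,n,calibration_target
L2/3,Exc,2.7,3.7,0.6,0.5,4.5,5,1
L2/3,PV,13.8,8.9,11.7,7.5,23.3,8,1
L2/3,SOM,2.6,3.6,0.4,0.03,4.1,9,1
L2/3,VIP,14.6,7.3,11.1,8.5,21.0,9,1
L4,Exc,0.5,0.8,,0.0,0.7,95,1
L4,PV,10.2,7.2,7.8,4.3,14.7,43,1
L4,SOM,2.6,3.2,0.6,0.3,4.9,27,1
L5,Exc,6.8,5.2,5.2,2.7,11.2,23,0
L5,PV,7.5,5.2,7.6,4.3,8.7,7,0
L5,SOM,2.8,4.5,0.8,0.2,3.6,18,0
L6,Exc,6.1,6.9,2.6,0.4,11.5,30,0
L6,PV,16.9,14.3,17.2,4.6,22.0,15,0
L6,SOM,3.9,4.9,1.7,0.5,6.9,26,0
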