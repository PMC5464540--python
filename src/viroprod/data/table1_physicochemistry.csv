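station,zone,depth_m,temperature_c,salinity,turbidity_ntu,po4_um,no2_um,no3_um,nh4_um,o2_um,h2s_um
Gotland Deep,oxic,80,4.77,9.32,0.06,2.2,0.3,1.0,1.0,41.4,n.d.
Gotland Deep,transition,90,5.25,10.18,0.1,3.6,0.7,n.d.,1.4,0.6,1.3
Gotland Deep,anoxic,95,5.32,10.34,0.31,3.5,0.4,n.d.,2.1,n.d.,3.2
Landsort Deep 1,suboxic,75,5.21,9.57,0.18,2.9,0.4,3.6,0.4,13.5,n.d.
Landsort Deep 1,transition,85,5.42,9.95,0.09,3.5,0.2,n.d.,3.1,1.3,0.2
Landsort Deep 1,anoxic,95,5.49,10.07,0.51,3.5,0.1,n.d.,4.2,n.d.,4.6
Landsort Deep 2,transition,78,5.26,9.61,0.18,3.4,0.3,4.5,<0.1,4.4,0.4
Landsort Deep 2,anoxic_1,90,5.43,9.95,0.24,3.7,<0.1,<0.1,3.4,n.d.,0.3
Landsort Deep 2,anoxic_2,100,5.5,10.1,0.43,3.4,<0.1,n.d.,4.0,n.d.,4.0
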