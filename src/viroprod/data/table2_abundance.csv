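station,zone,prok_avg,prok_sd,virus_avg,virus_sd,vpr,prok_tt_undiluted_d,prok_tt_dilution_d,viral_tt_undiluted_d,viral_tt_dilution_d
Gotland Deep,oxic,2.1,0.1,1.9,0.3,90,2.0,3.6,6.5,42.3
Gotland Deep,transition,9.0,0.2,1.7,1.2,18,5.6,7.1,4.7,53.6
Gotland Deep,anoxic,7.3,0.3,1.5,0.4,20,4.3,7.7,11.8,69.8
Landsort Deep 1,suboxic,5.4,0.1,1.4,0.3,25,3.8,14.7,3.3,84.3
Landsort Deep 1,transition,9.8,0.3,1.6,0.2,16,6.2,8.1,2.0,27.9
Landsort Deep 1,anoxic,8.9,0.2,1.6,0.4,18,4.3,6.2,3.5,24.1
Landsort Deep 2,transition,5.4,0.1,1.2,0.5,22,4.6,10.6,2.4,25.0
Landsort Deep 2,anoxic_1,8.8,0.4,1.4,0.6,16,13.0,15.6,6.1,28.4
Landsort Deep 2,anoxic_2,9.3,0.3,1.5,0.9,16,1.9,7.0,5.4,37.2
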