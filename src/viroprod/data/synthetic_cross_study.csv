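study,prok_abundance,viral_abundance,vpr,vp,vtt_d,vt_per_d,burst_size,bs_method
synthetic study 1,23.7,55.5,23.4,51.56,4.5,0.223,29.0,TEM
synthetic study 2,4.6,117.2,252.7,45.74,10.7,0.094,9.3,empirical
synthetic study 3,5.6,56.8,101.7,22.44,10.5,0.095,13.1,TEM
synthetic study 4,20.0,99.6,49.7,26.77,15.5,0.064,5.6,empirical
synthetic study 5,17.5,12.3,7.0,49.71,1.0,0.967,58.1,TEM
synthetic study 6,23.2,45.8,19.7,58.25,3.3,0.305,26.8,empirical
synthetic study 7,23.8,27.4,11.5,28.16,4.1,0.247,26.5,TEM
synthetic study 8,6.3,83.6,132.2,44.76,7.8,0.129,12.1,empirical
synthetic study 9,11.1,47.6,42.8,28.33,7.0,0.143,21.0,TEM
synthetic study 10,5.6,59.7,105.9,13.85,18.0,0.056,7.7,empirical
synthetic study 11,14.2,100.8,70.8,42.11,10.0,0.1,12.9,TEM
synthetic study 12,25.3,97.5,38.6,23.43,17.3,0.058,7.0,empirical
synthetic study 13,21.1,21.1,10.0,12.23,7.2,0.139,15.0,TEM
synthetic study 14,24.0,81.5,33.9,42.4,8.0,0.125,12.1,empirical
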