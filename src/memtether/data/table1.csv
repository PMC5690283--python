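construct,linker_aa,ca_uM,pip2_pct,dops_pct,f_eq_pN,f_eq_sd,Eb_kbt,Eb_sd,Eon_kbt,Eon_sd,log10_kb,log10_kb_sd,log10_kon,log10_kon_sd,log10_kub,log10_kub_sd
E-Syt2 C2AB,81,100,5,10,2.9,0.1,4.6,0.1,6.6,0.1,3.5,0.1,4.3,0.1,1.5,0.1
E-Syt2 C2AB,81,100,5,20,3.6,0.4,7,1,9,1,4.1,0.3,4.9,0.3,1.1,0.2
E-Syt2 C2C,40,0,5,10,6.5,0.6,12,1,14,1,5.2,0.9,6.1,0.9,-0.2,0.2
E-Syt2 C2C,40,0,2.5,10,5.7,0.3,10.2,0.6,12.5,0.6,4.3,0.2,5.3,0.2,-0.1,0.1
Syt1 C2AB,73,100,5,10,4.7,0.2,10.8,0.8,12.8,0.8,4.6,0.4,5.4,0.4,0,0.2
Syt1 C2AB,73,100,2.5,10,3.5,0.1,7.8,0.2,9.8,0.2,4.1,0.3,4.9,0.3,0.7,0.3
Syt1 C2AB,73,100,0,30,3.8,0.2,8.7,0.3,10.7,0.3,4.2,0.3,5.0,0.3,0.4,0.3
Syt1 C2B,66,100,5,10,3.1,0.2,7.4,0.5,9.4,0.5,4.2,0.2,5.1,0.2,1.0,0.3
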