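taxon,specimen_id,ecd_mm,bcl_mm,best_hz,mean_hz,recomputable_best,recomputable_mean,source
Baryonyx,NHMUK PV R9951,19.6,104.5,2538,1594,True,True,this study
Ceratosuchops,IWCMS 2014.95.3,17.7,106.8,2210,1416,True,True,this study
Irritator,SMNS 58022,18.1,75.3,3196,1950,True,False,Schade et al. 2020
Viavenator,MAU Pv LI 530,15.5,99.1,2057,1333,True,True,this study
Sinraptor,IVPP 10600,17.8,102.7,2329,1480,True,True,this study
Murusraptor,MCF PVPH 411,19.2,75.3,3352,2036,True,True,this study
Erlikosaurus,IGM 100.111,11.1,55.2,2723,1694,True,True,this study
Velociraptor,IGM 100/976,11.15,34.71,3965,2368,False,True,King et al. 2020
Velociraptor,IGM 100/0977,7.44,24.66,3798,2278,True,True,Hanson et al. 2021
Alioramus,IGM 100/1844,17.88,104.63,2292,1460,False,True,Hanson et al. 2021
Citipati,IGM 100/3006,8.75,21.42,4602,2713,True,True,Hanson et al. 2021
Byronosaurus,IGM 100/0983,7.97,19.24,4639,2733,True,True,Hanson et al. 2021
Troodontidae indet,IGM 100/3500,6.68,15.54,4737,2787,True,True,Hanson et al. 2021
Thecodontosaurus,YPM 2192,9.3,40.28,3089,1893,True,True,Ballell et al. 2021
Phuwiangosaurus,SM K11-006,9.48,NA,1687,1132,False,False,Kaikaew et al. 2022
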