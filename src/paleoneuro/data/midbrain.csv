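taxon,specimen_id,midbrain_mm,medulla_mm,ratio,recomputable,source
Sinosaurus,NA,50.2,52.5,0.96,True,Xing et al. 2014: Fig. 6A
Majungasaurus,NA,52.8,36.2,1.46,True,Sampson and Witmer 2007: Fig. 18A
Viavenator,NA,49.8,41.7,1.19,True,Paulina-Carabajal and Filippi 2018: Fig. 4
Baryonyx,NHMUK PV R9951,61.6,46.9,1.31,True,this study
Ceratosuchops,IWCMS 2014.95.1-3,61.1,49.9,1.22,True,this study
Allosaurus,NA,58.9,38.6,1.53,True,Witmer and Ridgely 2009: Fig. 4
Acrocanthosaurus,NA,55.6,44,1.26,True,Franzosa and Rowe 2005: 2B
Murusraptor,NA,33.5,32,1.05,True,Paulina-Carabajal and Currie 2018: Fig. 7.4
Tyrannosaurus,NA,40.7,50.9,0.8,True,Witmer and Ridgely 2009: Fig. 4
Erlikosaurus,NA,20.4,27.7,0.74,True,Lautenschlager et al. 2012: Fig. 3
Deinonychus,NA,16.3,20.7,0.79,True,Witmer and Ridgely 2009: Fig. 4
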