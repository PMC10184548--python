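taxon,group,ratio_pct,bulb_mm,cerebrum_mm,recomputable,source
Ceratosuchops,Spinosauridae,50.6,26.4,52.2,True,this study
Ceratosaurus,Ceratosauria,48.1,NA,NA,False,Zelenitsky et al. 2009
Majungasaurus,Ceratosauria,48.3,NA,NA,False,Zelenitsky et al. 2009
Carnotaurus,Ceratosauria,50,NA,NA,False,Cerroni and Paulina-Carabajal 2019
Viavenator,Ceratosauria,57,NA,NA,False,Paulina-Carabajal and Filippi 2018
Allosaurus,Allosauroidea,50-51.6,NA,NA,False,Zelenitsky et al. 2009
Acrocanthosaurus,Allosauroidea,58.1,NA,NA,False,Zelenitsky et al. 2009
Carcharodontosaurus,Allosauroidea,56,NA,NA,False,Zelenitsky et al. 2009
Giganotosaurus,Allosauroidea,57.7,NA,NA,False,Zelenitsky et al. 2009
Sinraptor,Allosauroidea,55,NA,NA,False,Cerroni and Paulina-Carabajal 2019
Dilong,Tyrannosauroidea,27,NA,NA,False,Zelenitsky et al. 2009
Tarbosaurus,Tyrannosauroidea,65.1-67.4,NA,NA,False,Zelenitsky et al. 2009
Tyrannosaurus,Tyrannosauroidea,68.3-71,NA,NA,False,Zelenitsky et al. 2009
Murusraptor,Tyrannosauroidea,45-50,NA,NA,False,Paulina-Carabajal and Currie 2018
Ornithomimosauria,Ornithomimosauria,28.2-32.5,NA,NA,False,Zelenitsky et al. 2009
Oviraptoridae,Oviraptoridae,31.5,NA,NA,False,Zelenitsky et al. 2009
Dromaeosauridae,Dromaeosauridae,28.5-36,NA,NA,False,Zelenitsky et al. 2009
Troodontidae,Troodontidae,32.6-33.5,NA,NA,False,Zelenitsky et al. 2009
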