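taxon,ev_cm3,ev37_cm3,ev50_cm3,mbd_g,req37,req50,recomputable,note,source
Baryonyx,150.5,55.7,75.3,2011000,1.2,1.6,True,NA,this study
Carnotaurus,169.8,62.8,84.9,1419000-1743000,1.4-1.6,1.9-2.2,False,body mass given as a range,Cerroni and Paulina-Carabajal 2019
Majungasaurus,106.4,39.4,53.2,1130000,1.14,1.54,True,NA,Cerroni and Paulina-Carabajal 2019
Ceratosaurus,NA,NA,NA,NA,1.2,1.7,False,literature REQ only; no EV or body mass printed,Cerroni and Paulina-Carabajal 2019
Allosaurus,169-188,62.5-69.5,84.5-93.9,1400000-2300000,1.3-1.8,1.8-2.4,False,EV and body mass given as ranges,Cerroni and Paulina-Carabajal 2019
Sinraptor,95,35.1,47.5,1700000,0.8,1.1,True,printed 37% volume (35.1) is 0.1 below 0.37*EV,Cerroni and Paulina-Carabajal 2019
Giganotosaurus,275,101.7,137.5,7000000,1.1,1.4,False,EV at 37% and 50% misreported in the source per the table note; REQ at 50% does not re-derive,Cerroni and Paulina-Carabajal 2019
Murusraptor,148.2,54.8,74.1,1551000,1.33,1.8,True,NA,Cerroni and Paulina-Carabajal 2019
Tyrannosaurus,414.2,153.2,207.1,5654000-7000000,1.8-1.6,2.5-2.2,False,body mass given as a range; REQ printed high-to-low,Cerroni and Paulina-Carabajal 2019
Gorgosaurus,128.9,47.7,64.5,1100000,1.4,1.9,True,NA,Cerroni and Paulina-Carabajal 2019
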