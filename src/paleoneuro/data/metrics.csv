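taxon,specimen_id,preserved_length_mm,length_excl_olfactory_mm,endocast_volume_cm3,cerebral_width_mm,cephalic_flexure_deg,pontine_flexure_deg,incomplete_fields,source
Baryonyx,NHMUK PV R9951,128.4,128.4,150.487,47.5,63,55,preserved_length_mm;endocast_volume_cm3,this study
Ceratosuchops,IWCMS 2014.95.1-3,173.5,122.2,185.603,47.9,78,66,NA,this study
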