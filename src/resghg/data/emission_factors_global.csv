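zone,pathway,flux,margin,provenance
Cool temperate moist dry,co2_diffusive,374.00,,global
Cool temperate moist dry,ch4_diffusive,151.73,,global
Cool temperate moist dry,ch4_ebullition,136.40,,global
Cool temperate moist dry,ch4_degassing,21.33,,global
Polar moist boreal dry moist,co2_diffusive,344.67,,global
Polar moist boreal dry moist,ch4_diffusive,69.52,,global
Polar moist boreal dry moist,ch4_ebullition,24.71,,global
Polar moist boreal dry moist,ch4_degassing,3.28,,global
Tropical dry montane,co2_diffusive,1081.67,,global
Tropical dry montane,ch4_diffusive,532.77,,global
Tropical dry montane,ch4_ebullition,800.38,,global
Tropical dry montane,ch4_degassing,869.13,,global
Tropical wet moist,co2_diffusive,1015.67,,global
Tropical wet moist,ch4_diffusive,540.22,,global
Tropical wet moist,ch4_ebullition,315.30,,global
Tropical wet moist,ch4_degassing,877.43,,global
Warm temperate dry,co2_diffusive,623.33,,global
Warm temperate dry,ch4_diffusive,222.13,,global
Warm temperate dry,ch4_ebullition,443.58,,global
Warm temperate dry,ch4_degassing,62.90,,global
Warm temperate moist,co2_diffusive,535.33,,global
Warm temperate moist,ch4_diffusive,231.44,,global
Warm temperate moist,ch4_ebullition,201.89,,global
Warm temperate moist,ch4_degassing,79.55,,global
Tropical dry montane,co2_diffusive,859,20,myanmar_all
Tropical dry montane,ch4_diffusive,387,27,myanmar_all
Tropical dry montane,ch4_ebullition,502,59,myanmar_all
Tropical dry montane,ch4_degassing,1337,211,myanmar_all
Tropical wet moist,co2_diffusive,612,26,myanmar_all
Tropical wet moist,ch4_diffusive,285,21,myanmar_all
Tropical wet moist,ch4_ebullition,304,39,myanmar_all
Tropical wet moist,ch4_degassing,1066,218,myanmar_all
Warm temperate dry,co2_diffusive,429,48,myanmar_all
Warm temperate dry,ch4_diffusive,145,27,myanmar_all
Warm temperate dry,ch4_ebullition,106,34,myanmar_all
Warm temperate dry,ch4_degassing,500,132,myanmar_all
Tropical wet moist,co2_diffusive,506,43,myanmar_hp
Tropical wet moist,ch4_diffusive,173,19,myanmar_hp
Tropical wet moist,ch4_ebullition,125,21,myanmar_hp
Tropical wet moist,ch4_degassing,834,234,myanmar_hp
Warm temperate dry,co2_diffusive,416,54,myanmar_hp
Warm temperate dry,ch4_diffusive,118,14,myanmar_hp
Warm temperate dry,ch4_ebullition,74,24,myanmar_hp
Warm temperate dry,ch4_degassing,432,143,myanmar_hp
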