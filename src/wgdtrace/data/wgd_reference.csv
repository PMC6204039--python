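event,lineage,ks_low,ks_high,source
gamma,Vitis vinifera,1.0,1.45,Tang2008
gamma,Populus trichocarpa,1.2,1.8,Tang2008
salicoid,Populus trichocarpa,0.15,0.4,Vanneste2014;Tang2008
gamma,Glycine max,1.3,1.7,Schmutz2010
early-legume,Glycine max,0.40,0.80,Schmutz2010
soybean-specific,Glycine max,0.06,0.39,Schmutz2010
T,Solanum lycopersicum,0.4,1.0,Vanneste2014;TomatoGenome2012
T,Solanum tuberosum,0.4,1.0,Vanneste2014
tau,Elaeis guineensis,0.9,1.3,Jiao2014
P,Elaeis guineensis,0.3,0.45,Jiao2014
rho,Oryza sativa,0.6,1.0,Vanneste2014;Jiao2014
rho,Sorghum bicolor,0.6,1.3,Vanneste2014
Pp-WGD,Physcomitrella patens,0.5,0.9,Rensing2008
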