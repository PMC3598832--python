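species,n,sl_mm,il_mm,pct_animal,config_state,trophic_class
Amniataba_caudavittatus,12,93.9,85.4,93,two_loop,Invertivore
Amniataba_percoides,28,110.5,112.8,44.2,two_loop,Omnivore
Bidyanus_welchi,9,204.1,347.2,70,six_loop,Generalist carnivore
Hannia_greenwayi,10,81.2,74.0,76.8,two_loop,Invertivore
Helotes_sexlineatus,36,123.4,177.3,22,helotes_type,Herbivore
Hephaestus_fuliginosus,20,266.9,556.3,32.8,six_loop,Omnivore
Hephaestus_carbo,25,129.2,126.7,98.6,two_loop,Invertivore
Hephaestus_epirrhinos,3,223.7,303.0,80.4,two_loop,Generalist carnivore
Hephaestus_jenkinsi,22,195.9,415.7,45.1,six_loop,Omnivore
Hephaestus_transmontanus,20,76.8,51.65,99.6,two_loop,Invertivore
Hephaestus_tulliensis,14,171.5,439.6,23.3,six_loop,Omnivore
Leiopotherapon_aheneus,18,50.7,96.3,31.9,aheneus_type,Herbivore
Leiopotherapon_unicolor,30,136.8,122.6,91.1,two_loop,Generalist carnivore
Mesopristes_argenteus,13,156.7,188.2,96.2,two_loop,Generalist carnivore
Pelates_quadrilineatus,7,112.7,106.6,99.2,two_loop,Generalist carnivore
Pelates_sexlineatus,16,94.9,85.1,98.1,two_loop,Generalist carnivore
Pelsartia_humeralis,2,153.5,142,96,two_loop,Generalist carnivore
Pingalla_gilberti,29,67.5,117.0,17.4,pingalla_type,Detritivore-algivore
Pingalla_lorentzi,12,67.1,122.5,34,pingalla_type,Detritivore-algivore
Scortum_ogilbyi,17,275.0,1297.6,8,scortum_type,Herbivore
Scortum_parviceps,28,264.0,1427.8,3,scortum_type,Herbivore
Syncomistes_butleri,18,200.0,786.5,0.2,syncomistes_type,Detritivore-algivore
Syncomistes_rastellus,12,108.4,415.4,7.7,syncomistes_type,Detritivore-algivore
Syncomistes_trigonicus,23,71.9,232.2,2.7,syncomistes_type,Detritivore-algivore
Terapon_jarbua,26,106.0,111.4,99,two_loop,Generalist carnivore
Terapon_puta,6,131.2,125.7,96.4,two_loop,Generalist carnivore
Terapon_theraps,8,148.9,144.8,99.9,two_loop,Generalist carnivore
Variichthys_lacustris,11,150.4,141.1,47,two_loop,Omnivore
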