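(((Terapon_jarbua,(Terapon_puta,Terapon_theraps)),((Pelates_quadrilineatus,Pelates_sexlineatus),(Pelsartia_humeralis,Helotes_sexlineatus))),(Mesopristes_argenteus,(Amniataba_caudavittatus,(((Leiopotherapon_unicolor,Leiopotherapon_aheneus),((Hannia_greenwayi_1,(Amniataba_percoides,Hannia_greenwayi_2)),(Variichthys_lacustris,(Hephaestus_carbo,Hephaestus_transmontanus)))),((Bidyanus_welchi,(Hephaestus_fuliginosus,(Hephaestus_jenkinsi,(Hephaestus_tulliensis,Hephaestus_epirrhinos)))),((Scortum_ogilbyi,Scortum_parviceps),((Pingalla_gilberti,Pingalla_lorentzi),(Syncomistes_butleri,(Syncomistes_rastellus,Syncomistes_trigonicus)))))))));
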