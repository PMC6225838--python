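family,species,common_name,origin,thermal_guild
Clupeidea,Clupea harengus,Herring,Marine,Cold
Cottidae,Triglopsis quadricornis,Fourhorn sculpin,Freshwater,Cold
Cyprinidae,Abramis bjoerkna,Silver bream,Freshwater,Warm
Cyprinidae,Abramis brama,Bream,Freshwater,Warm
Cyprinidae,Leuciscus idus,Ide,Freshwater,Warm
Cyprinidae,Rutilus rutilus,Roach,Freshwater,Warm
Osmeridae,Osmerus eperlanus,Smelt,Freshwater,Cold
Percidae,Gymnocephalus cernuus,Ruffe,Freshwater,Warm
Percidae,Perca fluviatilis,Perch,Freshwater,Warm
Pleuronectidae,Platichthys flesus,Flounder,Marine,
Salmonidae,Coregonus lavaretus,Whitefish,Freshwater,Cold
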