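trait,category,definition
Maximum size,Small,1-5 mm
Maximum size,Medium,6-30 mm
Maximum size,Large,>30 mm
Protection,No protection,
Protection,Tube,
Protection,Burrow,
Protection,Case,
Protection,Soft shell,
Protection,Hard shell,
Fragility,Fragile,
Fragility,Intermediate,
Fragility,Robust,
Environmental position,Infauna deep,>5 cm
Environmental position,Infauna middle,within 2-5 cm
Environmental position,Infauna top,top 2 cm
Environmental position,Epibenthic,
Environmental position,Benthic pelagic,
Energy content,Low,<1.7 kJ/g wwt
Energy content,Medium energy,1.7-3.4 kJ/g wwt
Energy content,High,3.4-5.1 kJ/g wwt
Movement,Swimming,
Movement,Surface crawling,
Movement,Burrowing,
Protruding,Sediment protruding,
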