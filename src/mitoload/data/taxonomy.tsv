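species	family
Balaena mysticetus	Balaenidae
Eubalaena glacialis	Balaenidae
Eubalaena japonica	Balaenidae
Eubalaena australis	Balaenidae
Balaenoptera musculus	Balaenopteridae
Balaenoptera physalus	Balaenopteridae
Tursiops australis	Delphinidae
Tursiops truncatus	Delphinidae
Delphinus delphis	Delphinidae
Pseudorca crassidens	Delphinidae
Tursiops aduncus	Delphinidae
Orcaella brevirostris	Delphinidae
Orcinus orca	Delphinidae
Peponocephala electra	Delphinidae
Globicephala macrorhynchus	Delphinidae
Stenella longirostris	Delphinidae
Stenella attenuata	Delphinidae
Delphinapterus leucas	Monodontidae
Monodon monoceros	Monodontidae
Phocoena spinipinnis	Phocoenidae
Phocoena dalli	Phocoenidae
Neophocaena phocaenoides	Phocoenidae
Phocoena phocoena	Phocoenidae
Neophocaena asiaeorientalis	Phocoenidae
Physeter macrocephalus	Physeteridae
Platanista gangetica	Platanistidae
Mesoplodon densirostris	Ziphiidae
Ziphius cavirostris	Ziphiidae
Mesoplodon europaeus	Ziphiidae
Mesoplodon grayi	Ziphiidae
Mesoplodon mirus	Ziphiidae
Hyperoodon ampullatus	Ziphiidae
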