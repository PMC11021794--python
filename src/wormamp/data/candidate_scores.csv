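id,species,accession,description,length,camp_top_hit,camp_evalue,ampir_precursor,ampir_mature,multipep_antimicrobial,multipep_antibacterial
Hmet,Haemonchus contortus,A0A7I4Y4R3,Metridin-ShK toxin,84,,,0.996,,0.746,0.215
Tchis,Toxocara canis,A0A0B2V2B5,Histone 2A,126,Histone H2A,4e-75,0.992,,0.325,0.958
Tdes,Teladorsagia circumcincta,A0A2G9TVU4,Destabilase (Lysozyme),139,Lysozyme 3,4e-39,0.923,,0.440,0.049
Tsap,Teladorsagia circumcincta,transcript/25448 (iso-seq),Saposin-b,104,Caenopore-5,2e-9,0.864,,0.943,0.279
Tscp,Teladorsagia circumcincta,A0A2G9TU46,SCP-like protein,166,,,0.732,,0.003,0.000
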