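phylum	order	family	species	rank	best_identity	presence_pct	mean_abundance_pct	se_abundance_pct	jacobs_D	se_D	category
Annelida	Phyllodocida	Nereididae	Hediste diversicolor	species	0.98	30.8	7.1	4.5	0.9	0.0	Medium
Annelida	Spionida	Spionidae	Scolelepis foliosa	species	1.00	5.8	0.7	0.6	1.0	0.0	Low
Annelida	Terebellida	Terebellidae	Pista cristata	species	0.99	21.2	4.5	2.6	0.6	0.2	Medium
Arthropoda	Amphipoda	Corophiidae	Corophium volutator	species	0.99	28.8	13.8	5.9	1.0	0.0	High
Arthropoda	Amphipoda	Pontoporeiidae	Bathyporeia sarsi	species	1.00	7.7	3.5	2.5	1.0	0.0	Medium
Arthropoda	Amphipoda	Talitridae	Talitrus saltator	species	0.99	1.9	0.8	0.8	1.0	0.0	Low
Arthropoda	Calanoida	Centropagidae	Centropages typicus	species	1.00	5.8	0.7	0.7	1.0	0.0	Low
Arthropoda	Decapoda	Carcinidae	Carcinus maenas	species	1.00	55.8	8.0	3.3	1.0	0.0	High
Arthropoda	Decapoda	Porcellanidae	Pisidia longicornis	species	1.00	9.6	1.7	1.5	1.0	0.0	Medium
Arthropoda	Diptera	Chironomidae	Unassigned	family	0.88	53.8	0.9	0.4	0.8	0.1	Medium
Arthropoda	Diptera	Chironomidae	Chironomus salinarius	species	1.00	1.9	1.3	1.3	1.0	0.0	Low
Arthropoda	Mysida	Mysidae	Mesopodopsis slabberi	species	0.99	3.8	0.6	0.6	1.0	0.0	Low
Arthropoda	Mysida	Mysidae	Neomysis integer	species	0.98	13.5	2.7	2.1	1.0	0.0	Medium
Arthropoda	Mysida	Mysidae	Schistomysis ornata	species	0.98	1.9	1.6	1.6	1.0	0.0	Low
Arthropoda	Sessilia	Austrobalanidae	Austrominius modestus	species	1.00	17.3	2.0	1.5	1.0	0.0	Medium
Chordata	Atheriniformes	Atherinidae	Atherina presbyter	species	1.00	1.9	0.6	0.6	1.0	0.0	Low
Chordata	Clupeiformes	Clupeidae	Sardina pilchardus	species	1.00	3.8	0.6	0.6	1.0	0.0	Low
Chordata	Pleuronectiformes	Scophthalmidae	Zeugopterus punctatus	species	0.99	3.8	0.8	0.6	1.0	0.0	Low
Chordata	Scombriformes	Scombridae	Scomber scombrus	species	1.00	1.9	1.0	1.0	1.0	0.0	Low
Chordata	Spariformes	Sparidae	Spondyliosoma cantharus	species	1.00	7.7	0.6	0.4	1.0	0.0	Low
Cnidaria	Actiniaria	Actiniidae	Anthopleura elegantissima	species	0.99	3.8	0.6	0.6	1.0	0.0	Low
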