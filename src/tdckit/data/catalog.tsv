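species	accession	class
Actaea racemosa	ADD71923	TDC
Actaea racemosa	ADD71924	TDC
Actaea racemosa	CCO62221	TDC
Camptotheca acuminata	AAB39708	TDC
Camptotheca acuminata	AAB39709	TDC
Capsicum annuum	ACN62126	TDC
Capsicum annuum	ACN62127	TDC
Catharanthus roseus	P17770	TDC
Mitragyna speciosa	AEQ01059	TDC
Ophiorrhiza prostrata	ABU40982	TDC
Ophiorrhiza pumila	BAC41515	TDC
Rauvolfia verticillata	ADL28270	TDC
Tabernaemontana elegans	AEY82396	TDC
Vinca minor	AEY82397	TDC
Arabidopsis thaliana	NP_001078461	TYDC
Arabidopsis thaliana	NP_194597	TYDC
Arabidopsis thaliana	CAB56038	TYDC
Arabidopsis thaliana	NP_849999	TYDC
Argemone mexicana	ACJ76782	TYDC
Aristolochia contorta	ABJ16446	TYDC
Citrus aurantium	ACX29995	TYDC
Citrus reshni	ACX29990	TYDC
Citrus reshni	ACX29991	TYDC
Citrus reticulata	ACX29996	TYDC
Citrus sinensis	ACX29992	TYDC
Medicago truncatula	AES81613	TYDC
Medicago truncatula	AES81615	TYDC
Papaver somniferum	P54768	TYDC
Papaver somniferum	P54769	TYDC
Papaver somniferum	P54770	TYDC
Papaver somniferum	P54771	TYDC
Papaver somniferum	AAC61841	TYDC
Papaver somniferum	AAC61842	TYDC
Papaver somniferum	AAC61843	TYDC
Papaver somniferum	AAC61844	TYDC
Petroselinum crispum	Q06085	TYDC
Petroselinum crispum	Q06086	TYDC
Petroselinum crispum	Q06087	TYDC
Petroselinum crispum	Q06088	TYDC
Solanum tuberosum	AHI16967	TYDC
Thalictrum flavum	AAG60665	TYDC
Theobroma cacao	EOX96928	TYDC
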