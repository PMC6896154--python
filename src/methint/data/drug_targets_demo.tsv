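drug_id	drug_name	approval_status	target_gene
DX0001	Alphazine	approved	GENE0001
DX0002	Betaprofen	approved	GENE0001
DX0003	Gammalol	experimental	GENE0001
DX0004	Deltacillin	approved	GENE0003
DX0005	Epsilomab	other	GENE0003
DX0006	Zetatinib	approved	GENE0005
DX0007	Etaparib	experimental	GENE0005
DX0008	Thetazole	approved	GENE0007
DX0009	Iotastat	approved	GENE0009
DX0010	Kappamycin	experimental	GENE0009
DX0011	Lambdaprost	approved	GENE0011
DX0012	Mupirinol	approved	GENE0013
DX0013	Nuvastatin	other	GENE0015
DX0014	Ximeline	approved	GENE0101
DX0015	Omicronib	approved	GENE0102
DX0016	Pirasone	experimental	GENE0103
DX0017	Rhodantin	approved	GENE0002
DX0018	Sigmafenac	approved	GENE0004
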