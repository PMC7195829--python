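accession	name
IPR900001	Collagen_triple_helix
IPR900002	EGF_like
IPR900003	EGF_like_Ca_binding
IPR900004	Fibronectin_type1
IPR900005	Fibronectin_type2
IPR900006	Fibronectin_type3
IPR900007	Laminin_EGF
IPR900008	Laminin_G
IPR900009	Laminin_N
IPR900010	Thrombospondin_1
IPR900011	Thrombospondin_3
IPR900012	VWF_A
IPR900013	VWF_C
IPR900014	VWF_D
IPR900015	Fibrinogen_C
IPR900016	Link_domain
IPR900017	SPARC_Ca_binding
IPR900018	Nidogen_G2
IPR900019	TIMP_like
IPR900020	Kazal_type_inhibitor
IPR900021	Kunitz_inhibitor
IPR900022	PAN_apple
IPR900023	Sushi_CCP
IPR900024	CUB_domain
IPR900025	Discoidin_F58C
IPR900026	Olfactomedin_like
IPR900027	Netrin_C
IPR900028	WAP_fourdisulfide
IPR900029	Anaphylatoxin_CS
IPR900030	Frizzled_CRD
IPR900031	Follistatin_like
IPR900032	Insulin_GF_binding
IPR900033	Peptidase_M10_MMP
IPR900034	Peptidase_M12_astacin
IPR900035	ADAM_cysteine_rich
IPR900036	Hemopexin_repeat
IPR900037	Lectin_C_type
IPR900038	Galectin_CRD
IPR900039	Annexin_repeat
IPR900040	Cadherin_like
IPR900041	Integrin_beta_N
IPR900042	Leucine_rich_repeat_SLRP
IPR900043	Proteoglycan_core
IPR900044	Elastin_tropo
IPR900045	Fibrillin_TB
IPR900046	LTBP_8cys
IPR900047	Matrilin_coiled_coil
IPR900048	Tenascin_assembly
IPR900049	EMI_domain
IPR900050	Gla_domain
IPR900051	Somatomedin_B
IPR900052	Whey_acidic_protein
IPR900053	SCP_CAP_domain
IPR900054	Zona_pellucida
IPR900055	Osteopontin_like
IPR900056	SIBLING_acidic
IPR900057	Ficolin_collagen
IPR900058	C1q_domain
IPR900059	Complement_B_type
IPR900060	PLAC_domain
IPR900061	NTR_domain
IPR900062	Thyroglobulin_type1
IPR900063	Semaphorin_sema
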