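property	group1	group2	group3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
vdw_volume	GASTPDC	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
surface_tension	GQDNAHR	KTSEC	ILMFPWYV
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MPSTHY
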