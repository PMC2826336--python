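element_class	broad_category	iupac_pattern	tf_family	source
as1/ocs/TGA-like	as1/ocs/TGA-like	TGACG	bZIP	as1-ocs core
as1/ocs/TGA-like	as1/ocs/TGA-like	TGACGTCA	bZIP	as1-ocs palindrome
ABRE-like	ABRE-like	ACGTGKC	bZIP	ABA response element core
ABRE-like	ABRE-like	TACGTGTC	bZIP	ABRE motif A
DRE/CRT-like	DRE/CRT/rav1-like	RCCGAC	AP2/ERF	dehydration response element core
rav1-like	DRE/CRT/rav1-like	CAACA	AP2/ERF	RAV1 AP2-domain half site
GCC-box-like	GCC-box/JAre-like	GCCGCC	AP2/ERF	ethylene response GCC box
JAre-like	GCC-box/JAre-like	AGCCGCC	AP2/ERF	jasmonate-responsive GCC variant
MYB2-box-like	MYB2-box-like	YAACTG	R2R3-MYB	MYB2 binding site
GARE-like	GARE/pyrimidine-box-like	TAACARA	R1-MYB	gibberellin response element
pyrimidine-box-like	GARE/pyrimidine-box-like	CCTTTT	R1-MYB	pyrimidine box
W-box-like	W-box-like	TTGACY	WRKY	W box
MYC2-box-like	MYC2-box-like	CACATG	bHLH	MYC recognition site
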