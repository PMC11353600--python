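# Bundled cis-element dictionary: plant promoter/5'UTR elements with
# literature-standard IUPAC consensi and functional categories.
name	consensus	category	description
STRE	AGGGG	Abiotic and biological stresses	stress response element
ARE	AAACCA	Abiotic and biological stresses	anaerobic induction element
LTR	CCGAAA	Abiotic and biological stresses	low-temperature responsiveness
MBS	CAACTG	Abiotic and biological stresses	MYB binding site, drought inducibility
TC-rich_repeats	GTTTTCTTAC	Abiotic and biological stresses	defense and stress responsiveness
WUN-motif	AAATTTCCT	Abiotic and biological stresses	wound responsiveness
ABRE	ACGTG	Phytohormone response	abscisic acid responsiveness
CGTCA-motif	CGTCA	Phytohormone response	MeJA responsiveness
TGACG-motif	TGACG	Phytohormone response	MeJA responsiveness
TCA-element	CCATCTTTTT	Phytohormone response	salicylic acid responsiveness
GARE-motif	TCTGTTG	Phytohormone response	gibberellin responsiveness
ERE	ATTTCAAA	Phytohormone response	ethylene responsiveness
P-box	CCTTTTG	Phytohormone response	gibberellin responsiveness
CAT-box	GCCACT	Plant growth and development	meristem expression
O2-site	GATGACATGG	Plant growth and development	zein metabolism regulation
circadian	CAANNNNATC	Plant growth and development	circadian control
RY-element	CATGCATG	Plant growth and development	seed-specific regulation
G-box	CACGTG	Light responsiveness	light-responsive bZIP element
Box-4	ATTAAT	Light responsiveness	part of a conserved light-responsive module
GT1-motif	GGTTAA	Light responsiveness	light responsiveness
GATA-motif	AAGGATAAGG	Light responsiveness	part of a light-responsive element
TCT-motif	TCTTAC	Light responsiveness	part of a light-responsive element
MRE	AACCTAA	Light responsiveness	MYB binding site, light responsiveness
AE-box	AGAAACAA	Light responsiveness	part of a light-responsive module
CAAT-box	CCAAT	Other	common enhancer element
TATA-box	TATAAA	Other	core promoter element
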