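name	consensus	group	note
CAAT-box	CCAAT	promoter-related	core promoter element
TATA-box	TATAAA	promoter-related	core promoter element
ABRE	ACGTG	hormone-responsive	abscisic-acid responsiveness
As-1	TGACG	hormone-responsive	salicylic-acid / auxin responsiveness
CGTCA-motif	CGTCA	hormone-responsive	methyl-jasmonate responsiveness
GARE-motif	TCTGTTG	hormone-responsive	gibberellin responsiveness
AuxRR-core	GGTCCAT	hormone-responsive	auxin responsiveness
G-box	CACGTG	light-responsive	light responsiveness
TCT-motif	TCTTAC	light-responsive	light responsiveness
Sp1	GGGCGG	light-responsive	light responsiveness
DRE-core	RCCGAC	environmental-stress	dehydration responsiveness
MBS	CAACTG	environmental-stress	MYB drought-inducibility site
LTR	CCGAAA	environmental-stress	low-temperature responsiveness
ARE	AAACCA	environmental-stress	anaerobic induction
CAT-box	GCCACT	development	meristem expression
O2-site	GATGACATGG	development	zein metabolism regulation
MBSI	AAAAAACCGGT	site-binding	MYB binding site, flavonoid genes
Box-III	CATTTACACT	site-binding	protein binding site
MYB	CAACCA	other	MYB recognition site
MYC	CATTTG	other	MYC recognition site
STRE	AGGGG	other	stress-response element (non-canonical placeholder)
Unnamed-4	CTCC	other	uncharacterized element (non-canonical placeholder)
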