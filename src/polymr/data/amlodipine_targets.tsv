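# Amlodipine protein-target genes: L-type calcium channel subunits
# (CACNA1C, CACNB1), T-type (CACNA1I), N-type (CACNA1B), auxiliary
# subunit alpha-2/delta-3 (CACNA2D3), carbonic anhydrase 1 (CA1) and
# sphingomyelin phosphodiesterase 1 (SMPD1), per DrugBank DB00381.
# Coordinates are approximate GRCh38 gene spans (Ensembl); edit to match
# your datasets' build before any real analysis.
# build=GRCh38
gene	chromosome	start	end
CACNA1C	12	1970786	2697950
CACNB1	17	39166426	39194563
CACNA1I	22	39570023	39693653
CACNA1B	9	137889947	138136012
CACNA2D3	3	54122154	55074557
CA1	8	85327427	85379013
SMPD1	11	6390797	6395804
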