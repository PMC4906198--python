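# The eleven reference HLA-DR alleles whose quantitative pocket profiles anchor
# pan-specific profile synthesis.  The published quantitative matrices for these
# alleles are not redistributable, so only the allele names ship here; users who
# hold TEPITOPE-style matrices can attach them through the registry TSV format
# (columns: allele, pocket, pseudosequence, then the 20 score columns).
allele
DRB1*0101
DRB1*0301
DRB1*0401
DRB1*0402
DRB1*0404
DRB1*0701
DRB1*0801
DRB1*1101
DRB1*1302
DRB1*1501
DRB5*0101
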