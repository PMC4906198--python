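# 39 HLA-DR / peptide crystal complexes with annotated 9-mer binding cores.
# split: "test30" = 30-complex benchmark set, "heldout9" = 9 additional complexes.
# Peptide/core pairs follow the benchmark prediction listing; for five entries
# (1KLU, 2FSE, 2IPK, 1FYT, 2IAM) the summary listing of the same complexes pairs
# the PDB id with a different peptide.  Where the two listings disagree, the
# alternative peptide is recorded in alt_peptide; the benchmark pairing is used
# throughout because it is the one the annotated cores belong to.
pdb_id	allele	peptide	core	split	alt_peptide
1AQD	DRB1*0101	VGSDWRFLRGYHQYA	WRFLRGYHQ	test30
1PYW	DRB1*0101	XFVKQNAAALX	FVKQNAAAL	test30
1KLG	DRB1*0101	GELIGILNAAKVPAD	IGILNAAKV	test30
2FSE	DRB1*0101	GELIGTLNAAKVPAD	IGTLNAAKV	test30	AGFKGEQGPKGEPG
1KLU	DRB1*0101	AGFKGEQGPKGEPG	FKGEQGPKG	test30	GELIGTLNAAKVPAD
1SJH	DRB1*0101	PEVIPMFSALSEG	VIPMFSALS	test30
1SJE	DRB1*0101	PEVIPMFSALSEGATP	VIPMFSALS	test30
1T5W	DRB1*0101	AAYSDQATPLLLSPR	YSDQATPLL	test30
1T5X	DRB1*0101	AAYSDQATPLLLSPR	YSDQATPLL	test30
2IAN	DRB1*0101	GELIGTLNAAKVPAD	IGTLNAAKV	test30
2IPK	DRB1*0101	GELIGILNAAKVPAD	IGILNAAKV	test30	XPKWVKQNTLKLAT
1FYT	DRB1*0101	XPKWVKQNTLKLAT	WVKQNTLKL	test30	PKYVKQNTLKLAT
1R5I	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
1HXY	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
1JWM	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
1JWS	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
1JWU	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
1LO5	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
2ICW	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
2OJE	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
2G9H	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30
2IAM	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	test30	GELIGILNAAKVPAD
1A6A	DRB1*0301	PVSKMRMATPLLMQA	MRMATPLLM	test30
1J8H	DRB1*0401	PKYVKQNTLKLAT	YVKQNTLKL	test30
2SEB	DRB1*0401	AYMRADAAAGGA	MRADAAAGG	test30
1BX2	DRB1*1501	ENPVVHFFKNIVTPR	VHFFKNIVT	test30
1YMM	DRB1*1501	ENPVVHFFKNIVTPRGGSGGGGG	VHFFKNIVT	test30
1FV1	DRB5*0101	NPVVHFFKNIVTPRTPPPSQ	FKNIVTPRT	test30
1H15	DRB5*0101	GGVYHFVKKHVHES	YHFVKKHVH	test30
1ZGL	DRB5*0101	VHFFKNIVTPRTPGG	FKNIVTPRT	test30
4E41	DRB1*0101	GELIGILNAAKVPAD	IGILNAAKV	heldout9
1DLH	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	heldout9
1KG0	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	heldout9
3L6F	DRB1*0101	APPAYEKLSAEQSPP	YEKLSAEQS	heldout9
3PDO	DRB1*0101	KPVSKMRMATPLLMQALPM	MRMATPLLM	heldout9
3PGD	DRB1*0101	KMRMATPLLMQALPM	MRMATPLLM	heldout9
3S4S	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	heldout9
3S5L	DRB1*0101	PKYVKQNTLKLAT	YVKQNTLKL	heldout9
1HQR	DRB5*0101	VHFFKNIVTPRTP	FKNIVTPRT	heldout9
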