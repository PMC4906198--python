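# Published binding-core predictions on the benchmark complexes, as reported in
# the comparison tables: this method's own predictions ("ours") for all 39
# complexes, and the TEPITOPE / MultiRTA / NetMHCIIpan-2.0 predictions for the
# 30-complex benchmark set.  These are static reference values for comparison;
# none of these predictors is re-implemented here.  Empty cells mean the method
# was not reported for that complex.
pdb_id	split	ours	tepitope	multirta	netmhciipan20
1AQD	test30	WRFLRGYHQ	WRFLRGYHQ	WRFLRGYHQ	WRFLRGYHQ
1PYW	test30	FVKQNAAAL	FVKQNAAAL	FVKQNAAAL	FVKQNAAAL
1KLG	test30	IGILNAAKV	IGILNAAKV	IGILNAAKV	LIGILNAAK
2FSE	test30	IGTLNAAKV	IGTLNAAKV	IGTLNAAKV	IGTLNAAKV
1KLU	test30	FKGEQGPKG	FKGEQGPKG	FKGEQGPKG	FKGEQGPKG
1SJH	test30	VIPMFSALS	VIPMFSALS	VIPMFSALS	VIPMFSALS
1SJE	test30	VIPMFSALS	VIPMFSALS	VIPMFSALS	VIPMFSALS
1T5W	test30	SDQATPLLL	YSDQATPLL	SDQATPLLL	YSDQATPLL
1T5X	test30	SDQATPLLL	YSDQATPLL	SDQATPLLL	YSDQATPLL
2IAN	test30	IGTLNAAKV	IGTLNAAKV	IGTLNAAKV	IGTLNAAKV
2IPK	test30	IGILNAAKV	IGILNAAKV	IGILNAAKV	LIGILNAAK
1FYT	test30	WVKQNTLKL	WVKQNTLKL	WVKQNTLKL	WVKQNTLKL
1R5I	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1HXY	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1JWM	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1JWS	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1JWU	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1LO5	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
2ICW	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
2OJE	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
2G9H	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
2IAM	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
1A6A	test30	MRMATPLLM	MRMATPLLM	MRMATPLLM	MRMATPLLM
1J8H	test30	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL	YVKQNTLKL
2SEB	test30	MRADAAAGG	MRADAAAGG	MRADAAAGG	YMRADAAAG
1BX2	test30	VHFFKNIVT	VHFFKNIVT	VHFFKNIVT	VVHFFKNIV
1YMM	test30	VHFFKNIVT	VHFFKNIVT	VHFFKNIVT	VHFFKNIVT
1FV1	test30	KNIVTPRTP	FKNIVTPRT	VHFFKNIVT	FFKNIVTPR
1H15	test30	YHFVKKHVH	YHFVKKHVH	YHFVKKHVH	YHFVKKHVH
1ZGL	test30	KNIVTPRTP	FKNIVTPRT	VHFFKNIVT	FFKNIVTPR
4E41	heldout9	IGILNAAKV
1DLH	heldout9	YVKQNTLKL
1KG0	heldout9	YVKQNTLKL
3L6F	heldout9	YEKLSAEQS
3PDO	heldout9	KMRMATPLL
3PGD	heldout9	MRMATPLLM
3S4S	heldout9	YVKQNTLKL
3S5L	heldout9	YVKQNTLKL
1HQR	heldout9	FKNIVTPRT
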