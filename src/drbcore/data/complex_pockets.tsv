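# Observed pocket-lining residues for the 30 benchmark complexes, one column per
# pocket.  Cells are space-separated "<beta-chain position><residue letter>"
# annotations (e.g. "82N 85V"); empty cells mean no residue was annotated for
# that pocket in that complex.  These are observational compositions; the
# canonical per-pocket position lists live in pockets.tsv.  One run-together
# annotation pair in the 1YMM pocket-4 cell was normalised to space-separated
# form during transcription.
pdb_id	pocket1	pocket2	pocket3	pocket4	pocket5	pocket6	pocket7	pocket8	pocket9
1AQD	82N 85V 86G	77T 78Y 81H 82N	78Y	13F 74A 78Y	13F 71R	11L	47Y 61W 67L 70Q 71R	60Y 61W	9W 57D 61W
1PYW	82N 85V 86G 89F	77T 78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	11L 28E 61W 71R	60Y 61W	57D 61W
1KLG	82N 85V	78Y 81H 82N	78Y	13F 71R 78Y	13F 71R	11L	61W	60Y 61W	57D 61W
2FSE	82N 85V 86G 89F	77T 78Y 82N		13F 28E 70Q 71R 74A 78Y	13F 71R	71R	28E 47Y 61W 67L 71R	61W	57D
1KLU	82N 85V	78Y 81H 82N		13F 71R 78Y	13F 71R	11L	61W	60Y 61W	57D 61W
1SJH	82N	78Y 81H 82N		13F 26L 70Q 71R 74A 78Y	71R	11L	61W	60Y 61W	57D 61W
1SJE	82N	78Y 81H 82N	78Y	13F 26L 70Q 71R 74A 78Y	71R	11L	61W	60Y 61W	57D 60Y 61W
1T5W	82N 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	61W 71R	60Y 61W	9W 57D 61W
1T5X	82N 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	71R	11L	61W 71R	61W	57D 61W
2IAN	82N 85V	78Y 81H 82N	78Y	13F 70Q 74A 78Y	13F 70Q 71R	11L	61W 71R	61W	57D 61W
2IPK	82N 85V 86G 89F	77T 78Y 81H 82N		13F 70Q 71R 74A 78Y	71R	11L	47Y 61W 67L 71R	60Y 61W	9W 57D 61W
1FYT	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	28E 47Y 61W 67L 71R	60Y 61W	9W 57D 61W
1R5I	82N 85V 86G 89F	77T 78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	70Q 71R	11L	47Y 61W 67L 71R	61W	9W 57D 61W
1HXY	82N 85V 86G 89F	78Y 81H 82N		13F 70Q 71R 74A 78Y	71R	11L	28E 47Y 61W 67L 71R	60Y 61W	9W 57D 61W
1JWM	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	71R	11L	28E 47Y 61W 67L 71R	61W	57D 61W
1JWS	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	47Y 61W 67L 71R	61W	9W 57D 61W
1JWU	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	28E 47Y 61W 67L 71R	61W	9W 57D 61W
1LO5	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 78Y	13F 71R	11L	47Y 61W 67L 71R	61W	9W 57D 60Y 61W
2ICW	82N 85V 86G 89F	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	13F 71R	11L	28E 47Y 61W 67L 71R	61W	9W 57D 61W
2OJE	82N 85V 86G	77T 78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	70Q 71R	11L	28E 47Y 61W 67L 71R	61W	9W 57D 61W
2G9H	82N 85V 86G 89F	77T 78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	71R	11L 13F	28E 47Y 61W 67L 71R	60Y 61W	9W 57D 61W
2IAM	82N	78Y 81H 82N	78Y	13F 70Q 71R 74A 78Y	70Q 71R	11L	61W 67L 71R	60Y 61W	57D 61W
1A6A	82N 85V 86V	77T 78Y 81H 82N	78Y	13S 26Y 74R 78Y	71K 74R	11S 30Y	30Y 47F 61W 67L 71K	61W	9E 30Y 57D 61W
1J8H	82N 85V 86G 89F	77T 78Y 81H 82N	78Y	13H 26F 28D 70Q 74A 78Y	13H 70Q 71K	11V 13H 30Y	30Y 47Y 61W 67L	60Y 61W	37Y 57D 61W
2SEB	82N	77T 78Y 81H 82N		13H 26F 71K 78Y	13H 71K	30Y	30Y 47Y 61W	60Y 61W	61W
1BX2	82N 85V	77T 78Y 81H 82N	78Y	13H 26F 28D 70Q 74A 78Y	70Q	13R			57D 60Y 61W
1YMM	82N	77T 78Y 81H 82N	78Y	13R 26F 28D 70Q 74A 78Y	70Q	13R	61W 67I	61W	57D 61W
1FV1	82N 85V 86G 89F	78Y 81H 82N	78Y	13Y 71R 78Y	71R	13Y	61W 67L 71K	61W	57D
1H15	82N 89F	77T 78Y 81H 82N	78Y	13Y 71R 78Y	71R	11D 13Y 30D	61W		57D 60Y
1ZGL	82N 85V 89F	77T 78Y 81H 82N		13Y 26F 71R 78Y	13Y	13Y 28H 61W 71R	61W		57D 60Y 61W
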