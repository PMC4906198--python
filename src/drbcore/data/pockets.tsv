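# Canonical nine-pocket model of the HLA-DR binding groove.
# positions: beta-chain residue numbers lining each pocket (space separated).
# anchor: 1 if the pocket is one of the five anchor sites (1, 4, 6, 7, 9).
pocket	positions	anchor
1	82 85 86 89	1
2	77 78 81 82	0
3	78	0
4	11 13 26 28 70 71 74 78	1
5	11 13 28 70 71 74	0
6	11 13 28 70 71 74	1
7	11 28 30 47 61 67 70 71	1
8	60 61	0
9	9 30 37 57 60 61	1
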