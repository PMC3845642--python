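Species	RNase1	RNase2/3	RNase4	RNase5	RNase6	RNase7/8	RNase9	RNase10	RNase11	RNase12	RNase13	RNase14	RNase15	Others
Hs	1	2 (1)	1	1	1	2	1	1	1	1	1	(2)	(1)	0
Pt	1	2	1	1	1	2	1	1	1	1	1	(1)	(1)	0
Gg	1	2 (1)	1	1	1	1 (1)	1	1	1	1	1	(2)	(1)	0
Pp	1	2 (1)	1	1	1	2	1	1	1	1	1	(3)	(1)	0
Nl	1	1	1	0	1	1 (1)	1	1	1	1	1	0	(1)	0
Mmu	1	2	1	1	1	2	2	1	1	1	1	(2)	(1)	0
Cj	1	1	1	1	1	2	1	1	0	1	(1)	0	(1)	0
Mm	1	7 (11)	1	5 (3)	1	0	1	1	1	1	1	0	0	0
Rn	3	5 (1)	1	2	1	0	1	1	1	1	1	0	0	0
Hg	1 (4)	0	1	0	4 (3)	1 (1)	1	1	(1)	1	1	0	0	0
Cp	3 (1)	0	2	0	3 (2)	1 (1)	0	1	1	1	1	0	(1)	0
Oc	1	3	1	1 (1)	1	2	1	1	1	1	1	0	0	0
Bt	3	2 (1)	1 (1)	3	1	2 (1)	2 (1)	1	1	1	1	1	1	0
Ec	1	1 (1)	1 (1)	1	1	1 (1)	1	1	1	1	0	(1)	(1)	0
Cf	1	0	1	(1)	1 (1)	0	1	1	(1)	1	1	0	0	0
Am	1	0	1	1	5 (1)	1 (1)	1	1	1	1	1	(1)	0	0
Ml	7	2	11 (3)	7 (9)	1 (7)	1 (1)	1	1	1	1	1	(1)	(1)	0
La	1 (2)	(1)	1	(1)	3	1 (1)	1	1	1	1	1	(1)	0	0
Md	1	0	1	1	0	1	0	0	0	1	1 (1)	0	0	15 (1)
Oa	0	0	1	0	0	0	0	0	0	0	1	0	0	3
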