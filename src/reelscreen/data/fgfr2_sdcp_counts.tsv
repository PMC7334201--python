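protein	rs7895676_1	rs7895676_2	rs2981578_1	rs2981578_2	rs2981584_1	rs2981584_2
PARP-2	1	2	0	0	0	0
EFTUD2	9	7	3	6	0	0
MYH9	0	0	1	1	0	0
TEAD3	0	0	10	7	0	0
EXOSC1	3	1	1	1	0	0
HIST1H2AB	1	2	3	2	0	0
RANBP2	1	3	2	2	0	0
TEAD1	0	0	5	5	1	1
NFIB	0	0	3	1	8	4
SNRNP40	1	3	3	2	0	0
SERPINC1	1	1	0	0	0	0
TCERG1	3	3	1	1	0	0
EMG1	0	0	1	1	0	0
YBX3	0	0	6	4	0	0
MED24	3	3	2	2	0	0
C1QBP	0	0	1	1	0	0
TFAM	1	1	0	0	0	0
LAD1	1	2	2	1	0	0
C2orf49	2	1	1	1	0	0
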