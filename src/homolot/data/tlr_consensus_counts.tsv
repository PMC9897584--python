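# Tally of 100%-probability remote-homology incidences: number of TLR/Toll
# queries from each model organism whose hit lists contain the given
# P. damicornis candidate protein at a printed probability of 100.0.
# Rows: model organisms; columns: coral candidate proteins (short numeric ids).
organism	22934	22930	11599	9200	14109	17966	13021	15883	11734	21819	737	15877	9057
Human	5	5	10	7	4	3	3	2	2	2	1	1	0
Zebrafish	8	7	11	9	6	6	2	0	0	2	1	0	0
Frog	6	5	10	10	4	4	3	0	0	0	0	0	1
Chicken	7	7	9	9	2	2	1	0	0	0	0	1	0
Drosophila	9	9	7	9	2	3	2	0	0	1	0	1	0
C. elegans	1	0	1	1	2	4	0	0	0	0	0	0	0
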