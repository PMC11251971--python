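#name	curvature_wedge
#k	2
#units	degrees
#citation	Bolshoy A et al. (1991) PNAS 88:2312-2316 (wedge angles); Kabsch W, Sander C, Trifonov EN (1982) NAR 10:1097-1104 (twist)
#strand_symmetric	false
#columns	wedge	direction	twist
#window_len	21
AA	7.2	-154.0	35.62
AC	1.1	143.0	34.4
AG	8.4	2.0	27.7
AT	2.6	0.0	31.5
CA	3.5	-64.0	34.5
CC	2.1	-57.0	33.67
CG	6.7	0.0	29.8
CT	8.4	-2.0	27.7
GA	5.3	120.0	36.9
GC	5.0	180.0	40.0
GG	2.1	57.0	33.67
GT	1.1	-143.0	34.4
TA	0.9	0.0	36.0
TC	5.3	-120.0	36.9
TG	3.5	64.0	34.5
TT	7.2	154.0	35.62
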