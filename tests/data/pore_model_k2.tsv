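# micro 2-mer pore model for tests: level of state j is 50 + 5*j pA
kmer	level_mean	level_stdv
AA	50	2
AC	55	2
AG	60	2
AT	65	2
CA	70	2
CC	75	2
CG	80	2
CT	85	2
GA	90	2
GC	95	2
GG	100	2
GT	105	2
TA	110	2
TC	115	2
TG	120	2
TT	125	2
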