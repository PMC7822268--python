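# DNA:RNA hybrid nearest-neighbor parameters (1 M NaCl, 37 C),
# re-keyed by the DNA strand dinucleotide 5'->3' (the antisense oligo);
# the RNA target is the perfect complement. dH kcal/mol,
# dS cal/(mol K), dG37 kcal/mol. Single duplex-initiation term; no
# terminal-pair corrections are defined for this set.
dimer	dH	dS	dG37
AA	-11.5	-32.7	-1.4
AC	-7.8	-21.6	-1.1
AG	-7.0	-19.7	-0.9
AT	-8.3	-23.9	-0.9
CA	-10.4	-28.4	-1.6
CC	-12.8	-31.9	-2.9
CG	-16.3	-47.1	-1.7
CT	-9.1	-23.5	-1.8
GA	-8.6	-22.9	-1.5
GC	-8.0	-17.1	-2.7
GG	-9.3	-23.2	-2.1
GT	-5.9	-12.3	-2.1
TA	-7.8	-23.2	-0.6
TC	-5.5	-13.5	-1.3
TG	-9.0	-26.1	-0.9
TT	-7.8	-21.9	-1.0
init	1.9	-3.9	3.1
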