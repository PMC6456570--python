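#	hairpin loop free-energy penalties at 37 C, kcal/mol
#	loops longer than the table extrapolate as dG(n) = dG(x) + 1.75*R*T*ln(n/x)
loop_len	dg37
3	3.5
4	3.5
5	3.3
6	4.0
7	4.2
8	4.3
9	4.5
10	4.4
12	4.7
14	5.0
16	5.2
18	5.4
20	5.5
25	5.8
30	6.1
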