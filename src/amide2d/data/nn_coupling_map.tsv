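# Synthetic nearest-neighbour amide-I coupling surface J(phi, psi) in cm-1.
# Smooth periodic stand-in for published ab initio nearest-neighbour maps,
# calibrated to ~-7.5 cm-1 in the alpha-helical basin (-57,-47) and
# ~+4.5 cm-1 in the extended/beta basin (-139,135). Replaceable via config.
phi	psi	J
-180	-180	5.1676
-180	-150	9.7855
-180	-120	12.5049
-180	-90	12.5970
-180	-60	10.0373
-180	-30	5.5115
-180	0	0.2324
-180	30	-4.3855
-180	60	-7.1049
-180	90	-7.1970
-180	120	-4.6373
-180	150	-0.1115
-150	-180	9.7855
-150	-150	12.5049
-150	-120	12.5970
-150	-90	10.0373
-150	-60	5.5115
-150	-30	0.2324
-150	0	-4.3855
-150	30	-7.1049
-150	60	-7.1970
-150	90	-4.6373
-150	120	-0.1115
-150	150	5.1676
-120	-180	12.5049
-120	-150	12.5970
-120	-120	10.0373
-120	-90	5.5115
-120	-60	0.2324
-120	-30	-4.3855
-120	0	-7.1049
-120	30	-7.1970
-120	60	-4.6373
-120	90	-0.1115
-120	120	5.1676
-120	150	9.7855
-90	-180	12.5970
-90	-150	10.0373
-90	-120	5.5115
-90	-90	0.2324
-90	-60	-4.3855
-90	-30	-7.1049
-90	0	-7.1970
-90	30	-4.6373
-90	60	-0.1115
-90	90	5.1676
-90	120	9.7855
-90	150	12.5049
-60	-180	10.0373
-60	-150	5.5115
-60	-120	0.2324
-60	-90	-4.3855
-60	-60	-7.1049
-60	-30	-7.1970
-60	0	-4.6373
-60	30	-0.1115
-60	60	5.1676
-60	90	9.7855
-60	120	12.5049
-60	150	12.5970
-30	-180	5.5115
-30	-150	0.2324
-30	-120	-4.3855
-30	-90	-7.1049
-30	-60	-7.1970
-30	-30	-4.6373
-30	0	-0.1115
-30	30	5.1676
-30	60	9.7855
-30	90	12.5049
-30	120	12.5970
-30	150	10.0373
0	-180	0.2324
0	-150	-4.3855
0	-120	-7.1049
0	-90	-7.1970
0	-60	-4.6373
0	-30	-0.1115
0	0	5.1676
0	30	9.7855
0	60	12.5049
0	90	12.5970
0	120	10.0373
0	150	5.5115
30	-180	-4.3855
30	-150	-7.1049
30	-120	-7.1970
30	-90	-4.6373
30	-60	-0.1115
30	-30	5.1676
30	0	9.7855
30	30	12.5049
30	60	12.5970
30	90	10.0373
30	120	5.5115
30	150	0.2324
60	-180	-7.1049
60	-150	-7.1970
60	-120	-4.6373
60	-90	-0.1115
60	-60	5.1676
60	-30	9.7855
60	0	12.5049
60	30	12.5970
60	60	10.0373
60	90	5.5115
60	120	0.2324
60	150	-4.3855
90	-180	-7.1970
90	-150	-4.6373
90	-120	-0.1115
90	-90	5.1676
90	-60	9.7855
90	-30	12.5049
90	0	12.5970
90	30	10.0373
90	60	5.5115
90	90	0.2324
90	120	-4.3855
90	150	-7.1049
120	-180	-4.6373
120	-150	-0.1115
120	-120	5.1676
120	-90	9.7855
120	-60	12.5049
120	-30	12.5970
120	0	10.0373
120	30	5.5115
120	60	0.2324
120	90	-4.3855
120	120	-7.1049
120	150	-7.1970
150	-180	-0.1115
150	-150	5.1676
150	-120	9.7855
150	-90	12.5049
150	-60	12.5970
150	-30	10.0373
150	0	5.5115
150	30	0.2324
150	60	-4.3855
150	90	-7.1049
150	120	-7.1970
150	150	-4.6373
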