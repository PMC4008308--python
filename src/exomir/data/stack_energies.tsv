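# Nearest-neighbor stacking free energies, kcal/mol.
# outer = helix pair closer to the helix exterior, written (5' base, 3' base);
# inner = the pair stacked directly inside it. Watson-Crick entries follow
# published nearest-neighbor measurements; wobble-containing stacks are a
# deliberately weak flat term so that wobble pairing never outcompetes a
# Watson-Crick alternative.
outer	inner	energy
AT	AT	-0.93
AT	TA	-1.10
AT	CG	-2.24
AT	GC	-2.08
AT	GT	-0.60
AT	TG	-0.60
TA	AT	-1.33
TA	TA	-0.93
TA	CG	-2.35
TA	GC	-2.11
TA	GT	-0.60
TA	TG	-0.60
CG	AT	-2.11
CG	TA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GT	-0.60
CG	TG	-0.60
GC	AT	-2.35
GC	TA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GT	-0.60
GC	TG	-0.60
GT	AT	-0.60
GT	TA	-0.60
GT	CG	-0.60
GT	GC	-0.60
GT	GT	-0.40
GT	TG	-0.40
TG	AT	-0.60
TG	TA	-0.60
TG	CG	-0.60
TG	GC	-0.60
TG	GT	-0.40
TG	TG	-0.40
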