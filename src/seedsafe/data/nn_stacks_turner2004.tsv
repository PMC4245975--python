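# Nearest-neighbor helix stacking free energies, RNA, 37 C, Turner 2004 set.
# Units: dcal/mol (value/100 = kcal/mol).  Row = closing pair 5'X/3'Y, column =
# inner pair read 3'->5' on the top strand (standard folding-matrix convention):
# dG(5'-ab-3'/3'-a'b'-5') = table[pair(a,a')][pair(b',b)].
# G:U wobble columns/rows included; non-pairing combinations are absent.
pair	CG	GC	GU	UG	AU	UA
CG	-240	-330	-210	-140	-210	-210
GC	-330	-340	-250	-150	-220	-240
GU	-210	-250	130	-50	-140	-130
UG	-140	-150	-50	30	-60	-100
AU	-210	-220	-140	-60	-110	-90
UA	-210	-240	-130	-100	-90	-130
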