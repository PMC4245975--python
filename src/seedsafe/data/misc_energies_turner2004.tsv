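# Miscellaneous energy terms, RNA, 37 C, Turner 2004 set.  Units: dcal/mol
# except lxc (dcal/mol per ln-unit of loop size).
key	value
duplex_init	410
terminal_au	50
ml_closing	930
ml_branch	-90
ml_unpaired	0
ninio_per_nt	60
ninio_max	300
lxc	107.856
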