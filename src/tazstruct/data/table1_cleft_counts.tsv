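# Distribution over exons of the 57 residues lining the putative
# substrate-binding cleft of the human tafazzin (Δ5) model structure.
exon_id	count	fraction_pct
2	10	17.5
4	18	31.6
6	15	26.3
7	5	8.8
8	6	10.5
9	3	5.3
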