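# Protein-level exon boundaries for human tafazzin (full-length isoform,
# 292 aa, 11 exons). Exon 5 = 125-154 (30 residues, the alternatively
# spliced primate-specific exon) is exact; the remaining boundaries are
# approximate reconstructions constrained to place every curated missense
# variant in its literature-assigned exon (Gly80 kept in exon 2) and to
# keep the acyltransferase domain (41-245) spanning exons 2-10.
exon_id	start	end
1	1	39
2	40	80
3	81	100
4	101	124
5	125	154
6	155	180
7	181	196
8	197	225
9	226	239
10	240	260
11	261	292
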