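# Disease-causing missense mutations in human tafazzin (Barth syndrome),
# curated from the published clinical-mutation literature, with the
# structure-derived location class, electrostatic/stability flags and
# proposed functional effect for each variant (full-length numbering).
hgvs_p	exon	location	electrostatic	stability	effect
p.Asn40Asp	2	Surface	X		Membrane association
p.Thr43Pro	2	Buried		X	Destabilization
p.Leu50Pro	2	Buried		X	Destabilization
p.Ile54Asn	2	Surface		X	Membrane association
p.Arg57Leu	2	Surface	X		Membrane association
p.Pro62Leu	2	Cleft		X	Substrate binding
p.His69Gln	2	Catalytic site	X		Catalytic activity
p.Ser71Pro	2	Cleft		X	Substrate binding
p.Gly80Glu	2	Buried	X	X	Destabilization
p.Leu82Pro	3	Buried		X	Destabilization
p.Arg94Cys	3	Surface	X		Membrane association
p.Arg94Gly	3	Surface	X		Membrane association
p.Arg94Ser	3	Surface	X		Membrane association
p.Arg94His	3	Surface	X		Membrane association
p.Asp101Val	4	Cleft	X	X	Substrate binding
p.Phe104Val	4	Cleft		X	Substrate binding
p.Ser110Pro	4	Cleft		X	Substrate binding
p.Gly116Asp	4	Cleft	X	X	Substrate binding
p.Lys117Glu	4	Surface	X		Membrane association
p.Cys118Arg	4	Cleft	X	X	Substrate binding
p.Val119Gly	4	Cleft		X	Substrate binding
p.Gly124Arg	4	Cleft	X	X	Substrate binding
p.Phe128Ser	5	Cleft		X	Substrate binding
p.Gly161Arg	6	Cleft	X	X	Substrate binding
p.Leu169His	6	Cleft	X		Substrate binding
p.Trp174Gly	6	Cleft		X	Substrate binding
p.Phe178Ile	6	Cleft		X	Substrate binding
p.Val183Gly	7	Cleft		X	Substrate binding
p.Gly195Val	7	Cleft		X	Substrate binding
p.Gly197Arg	8	Cleft	X	X	Substrate binding
p.Gly197Glu	8	Cleft	X	X	Substrate binding
p.Gly197Trp	8	Cleft		X	Substrate binding
p.Gly197Val	8	Cleft		X	Substrate binding
p.Ile209Asp	8	Buried	X	X	Destabilization
p.Leu210Arg	8	Buried	X	X	Destabilization
p.Leu212Pro	8	Buried		X	Destabilization
p.His214Arg	8	Buried	X	X	Destabilization
p.Gly216Arg	8	Buried	X	X	Destabilization
p.Gly240Arg	10	Buried	X	X	Destabilization
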