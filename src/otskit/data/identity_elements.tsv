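# Identity-element catalog for host aaRS recognition screening of the pSer
# suppressor tRNA.  'source' marks rows encoding the study's stated elements
# (paper) versus literature-supplemented entries (Hasegawa; Nameki; Lenhard);
# extend freely.  flag_threshold is the minimum matched-element count that
# flags an aaRS; structural elements are always required regardless.
aars	kind	pos5	pos3	required	structural_feature	threshold	flag_threshold	source
GlyRS	base_pair	1	72	G:C			3	paper
GlyRS	base_pair	2	71	C:G			3	paper
GlyRS	base	73		U			3	paper
ThrRS	base_pair	1	72	G:C			3	paper
ThrRS	base_pair	2	71	C:G			3	paper
ThrRS	base	73		U			3	paper
SerRS	structural				variable_loop	10	3	literature
SerRS	base	73		G			3	literature
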