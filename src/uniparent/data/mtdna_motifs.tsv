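# Packaged mtDNA motif tree (rCRS coordinates, 1-based).
# Motifs marked * in the comment column of this header are the published
# defining motifs of the named sub-lineages; motifs of the backbone nodes
# above them (M, M5a1b, M35b2, H, U, U3b1) are abbreviated single-tag
# stand-ins sufficient to separate the packaged clades -- they are NOT the
# full reference-tree definitions.  Edit or extend freely; the classifier
# is tree-agnostic.
#   * M5a1b1a   = 3954T,9833C
#   * M5a1b1a1  = M5a1b1a + 16298C
#   * M5a1b1a2  = M5a1b1a + 15902C, without 16298C
#   * H107      = 1271G,3621C,16223T
name	parent	required	forbidden	origin
mt-MRCA	.	.	.	unassigned
M	mt-MRCA	10400T,14783C	.	unassigned
M5a1b	M	1888A	.	South Asian
M35b2	M	12561A	.	South Asian
M5a1b1a	M5a1b	3954T,9833C	.	South Asian
M5a1b1a1	M5a1b1a	16298C	.	South Asian
M5a1b1a2	M5a1b1a	15902C	16298C	South Asian
H	mt-MRCA	2706A,7028C	.	European
H107	H	1271G,3621C,16223T	.	European
U	mt-MRCA	12308G	.	European
U3b1	U	16343G	.	European
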