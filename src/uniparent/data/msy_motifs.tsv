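# Packaged MSY motif tree (GRCh38 chrY coordinates, 1-based).
# Only 26618569C is a published defining variant of the corresponding
# sub-branch; every other motif here is an abbreviated synthetic tag that
# stands in for SNP sets not enumerated in the open literature (the
# H1a1a4b2d-defining polymorphisms and sub-branch SNPs live in
# controlled-access supplementary tables).  Replace tags with real ISOGG
# positions for production use; the classifier is tree-agnostic.
name	parent	required	forbidden	origin
Y-MRCA	.	.	.	unassigned
H1a	Y-MRCA	7500001T	.	South Asian
H1a1a4b2	H1a	7600001C	.	South Asian
H1a1a4b2d	H1a1a4b2	7700001A	.	South Asian
H1a1a4b2d1	H1a1a4b2d	7800001G	.	South Asian
H1a1a4b2d2	H1a1a4b2d	7900001T	.	South Asian
H1a1a4b2d3	H1a1a4b2d	26618569C	.	South Asian
H1a1a4b2d3a	H1a1a4b2d3	8000001A	.	South Asian
J2a	Y-MRCA	8100001G	.	West Asian
J2a-M67	J2a	8200001T	.	West Asian
J2a-M92	J2a-M67	8300001C	.	West Asian
I1a	Y-MRCA	8400001A	.	European
I1a-Z140	I1a	8500001G	.	European
I1a-Z62	I1a-Z140	8600001T	.	European
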