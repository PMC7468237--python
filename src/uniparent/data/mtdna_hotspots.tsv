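# Default mtDNA site-exclusion list for network/distance analyses.
# One entry per line: a single rCRS position or an inclusive interval a-b.
# Covers the classic hypervariable length-heteroplasmy tracts and hotspot
# sites, plus the 941-942 insertion region. Edit or replace as needed.
309
315
523-524
941-942
3107
16182
16183
16193
16519
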