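# Template exclusion list for the two rRNA operons.
# Edit the gene ids to match the locus tags used by YOUR annotation
# (the first tab-separated column is the gene id, the second a free-text
# reason). Lines starting with '#' are ignored.
rrn16Sa	rRNA operon A
rrn23Sa	rRNA operon A
rrn5Sa	rRNA operon A
rrn16Sb	rRNA operon B
rrn23Sb	rRNA operon B
rrn5Sb	rRNA operon B
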