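category	n_genes
Total considered	938
No evidence for alternative transcripts	677
Alternative transcripts encode same protein	64
Alternative transcripts annotated to encode different isoforms	197
Alternative unique starting exon - strong evidence	21
Alternative unique starting exon - weak evidence	7
Nested alternative starts	22
Alternative terminal exon - strong evidence	0
Alternative terminal exon - weak evidence	23
Non-constitutive internal exon - strong evidence	0
Non-constitutive internal exon - weak evidence	5
Non-constitutive internal intron - strong evidence	3
Non-constitutive internal intron - weak evidence	3
Alternative splice site selection - strong evidence	4
Alternative splice site selection - weak evidence	20
Alternative transcripts by multiple mechanisms - strong evidence	9
Alternative transcripts by multiple mechanisms - weak evidence	25
Alternative transcript evidence considered invalid	55
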