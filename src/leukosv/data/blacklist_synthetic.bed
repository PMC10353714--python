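chr1	125184587	143184587	1q12_heterochromatin	gap
chr14	21621904	22552132	TRA	IG_TR
chr14	105586437	106879844	IGH	IG_TR
chr2	88857361	90235368	IGK	IG_TR
chr22	22026076	22922913	IGL	IG_TR
chr7	38240024	38368055	TRG	IG_TR
chr7	142299011	142813287	TRB	IG_TR
chr9	47000000	49500000	9q12_heterochromatin	gap
chrY	26600000	57227415	Yq12_heterochromatin	gap
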