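1	24980000	24984000	At1g66960	non_clustered
1	29530000	29534000	PEN6	non_clustered
1	29680000	29683000	At1g78950	non_clustered
1	29684000	29686000	At1g78955	non_clustered
1	29687000	29690000	At1g78960	non_clustered
1	29691000	29694000	At1g78970	non_clustered
2	2900000	2904000	CAS1	non_clustered
3	16490000	16494000	LAS1	non_clustered
4	8752000	8755000	At4g15340	clustered
4	8763000	8767000	At4g15370	clustered
5	14240000	14244000	PEN3	clustered
5	17040000	17044000	MRN	clustered
5	19455000	19458000	THAS	clustered
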