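name	cores	count	hours	rate_per_hour
Standard Small (single core)	1	50	1088	0.115
Standard Large (dual core)	2	50	544	0.46
Standard Extra Large (4-cores)	4	50	272	0.92
High-CPU Medium (dual core)	2	50	544	0.23
High-CPU Extra Large (8 core)	8	50	136	0.92
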