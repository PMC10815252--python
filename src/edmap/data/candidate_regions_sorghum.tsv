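chrom	start_mb	end_mb	size_mb	n_transcripts	n_genes
chr10	57.91461	58.149969	0.235359	30	24
chr1	1.154111	1.34952	0.195409	46	39
chr1	1.409762	1.532592	0.12283	49	30
chr1	1.623681	1.691337	0.067656	15	14
chr1	1.812801	1.938655	0.125854	38	31
chr1	4.068754	4.498218	0.429464	63	52
chr1	58.306682	59.217158	0.910476	87	65
chr1	65.020891	65.164125	0.143234	16	15
chr1	6.504078	6.639419	0.135341	24	16
chr1	67.295568	67.722791	0.427223	57	49
chr1	72.061557	72.655387	0.59383	85	67
chr1	8.567085	8.898033	0.330948	63	29
chr2	4.668026	5.149803	0.481777	76	59
chr2	5.400013	5.487665	0.087652	7	5
chr2	5.664728	5.793508	0.12878	21	11
chr2	71.663212	72.648182	0.98497	190	116
chr3	0.703708	1.323768	0.62006	104	85
chr3	70.882922	72.678683	1.795761	285	199
chr4	60.551245	60.866205	0.31496	45	29
chr6	23.890052	24.617971	0.727919	0	0
chr6	59.233376	59.338064	0.104688	22	20
chr8	58.306666	58.339277	0.032611	5	5
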