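category	redundant	unique
total	59541021	32574580
length_filtered	15178457	11922873
low_complexity	21131	6522
invalid	300657	229912
rRNA_tRNA	2455844	66367
putative_population	41584932	20348906
genome_mapped	12062113	3673564
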