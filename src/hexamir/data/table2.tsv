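name	mature	length	star	target	action
tae_1	AAACUAAUAUAUGAGCGUUUA	21	AAUGCUCUUAUAUUAGUUUAC	TC437556	C
tae_2	AAUUCGGGACGGAGGGAGUAA	21	ACUCCCUCCGUCCGGAAAUA	TC459057	C
tae_3	UUUCUGCGACGAGUAAUUCGG	21	AAUUACUCGUCGCAGAAAUGG	TC427972	C
tae_4	ACUUCCUCCGUUCGGAAUUAC	21	GUAAUUCCGAACGGAGGGAGUA	CV763629	C
tae_5	AGACAAGUAAUUUCGAACGGA	21	UCCGUUCGGAAUUACUUGUCG	TC390088	C
tae_6	AGCGAUCUGCCGAAGCUGUU	20	AUGCAUCGGUAGGGGAGCGU	FL645778	C
tae_7	AGGCCCACUGGGCAGCGCCCC	21	GCGCUGCCCUGUGAGCCUGC	CK160940	T
tae_8	AGUAAUUUUGGACGGAGGGAG	21	ACUCCCUCCGUCCGGAAUUA	CJ562562	C
tae_9	AUAAGCACCGGUGCUUAAGGA	21	CUGAAGCACCGGUGCCUAUUU	TC416715	C
tae_10	AUUAGUACUGGUUCGUGGCAC	21	GCCACGAACCGGUACUAAUGA	CA636114	C
tae_11	AUUUCUGGACGGAGGGAGUAA	21	ACUCCCUUCGUCCGGAAAUAC	BJ253379	C
tae_12	CAUCUAUUUUGGAACGGAGGG	21	UCCGUUCCAAAAUAGAUGACC	CK207929	C
tae_13	CCCUGGCAGAUAGCGCGAUCA	21	UGAACGGCACUUGCACAUGGG	TC402919	C
tae_14	CGCGCUGCCCUGUGAGCUUGC	21	AGGCCCACCGGGCAGCGCCC	TC400184	C
tae_15	CGGUAGGGCUGUAUGAUGGCGA	22	GCCAUCAUACGCCCAACCGUG	CJ881369	C
tae_16	UUUGACCAAGUUUGUAGAGAA	21	UUUUCUCUAUAAACUUGGUCA	CD452777	C
tae_17	CGGUUGGGCUGUAUGAUGGCGA	22	GCCAUCAUACGUCCAACCGUG	TC459829	C
tae_18	CUGACAUACGGGCGUGUGGGC	21	CGCCCACACGCACGCGUGUGAG	TC394522	C
tae_19	GGGCGUUCGCGCGGGCCGACC	21	UCGGCCUCGCGCUCGCCCUC	CA594286	C
tae_20	GGUGAACGCGCCGCCGUCAAAC	22	UUUGCCGGCGUGCGCGAGCACC	CA682386	C
tae_21	GGUGAGCGCGCCGCCGUCGAA	21	UUCGCCGGUCGCGCGUUCCCC	TC383147	T
tae_22	GUGCGCGGUCUGUUUUGGUCAG	22	GGCCGAGCGACGGACGGUGCCG	TC458773	C
tae_23	UAAUGUAAGACGCUUUUUGAC	21	UCAAAAAACGUCUUACAUUAU	CD881202	C
tae_24	UACCACGACUGUCAUUAAGCA	21	UGCUUAAUGACAGUCGUGGUG	AJ603583	C
tae_25	UAGCUCCACUAAAUUUGGAGCU	22	CUCCAAACUUAGUGAGCUAAG	CA698993	C
tae_26	UAUGGAUGAAGAUAUGCACUG	21	AGAAAGCAUUGUCUGACGUC	CJ882127	C
tae_27	UCCCGAAAGGCUUGAAGCAAAU	22	UAGCUUCAAGCCUUGAGGAAUA	TC435172	T
tae_28	UCUGAUUUACUCGUCGUGGUU	21	ACCACGACGAGUAAAUCGGAA	CD888727	C
tae_29	UCUGUAAACUAACAUAAGAGC	21	UCUUAUAUUAGUUUACGGAGG	No target	NA
tae_30	UCUGUAAACUAAUGUAAGAGC	21	UCUUAUAUUAGUUUACGGAGG	No target	NA
tae_31	UCUGUGACAAGUAAUUCCGAA	21	UCGGAAUUACUUGUCUCGGAU	CJ600810	C
tae_32	UCUUACAUUAUGGGACGGAGU	21	UCCGUCCCAUAAUGUAAGACG	TC433469	C
tae_33	UGAACGUGUGCUGAACGCGGA	21	UGCGUUCGGUACUUGAUCGG	CA683773	C
tae_34	UGACAAAUAUUUUCGGACGGA	21	CCUCCGUCCGGAAAUACUUG	CJ715057	C
tae_35	UGACAACUAUUUUCGGACGGA	21	UCCGUCCGGAAAUACUUGUCA	BJ276292	C
tae_36	UGACAAGUACUUUCGGACGGA	21	UCCGUCCGGAAAUACUUGUCA	BJ276292	T
tae_37	UGACAAGUAUUCUCGGACGGA	21	UCCGUCCGGAAAUACUUGUCA	TC433218	C
tae_38	UGACAAGUAUUUCGGACGGA	20	UCUGUCCGGAAAUACUUGUCA	BJ276292	T
tae_39	UGACAAGUAUUUUCGAACGGA	21	UCCGUCCGGAAAUACUUGUCA	BE423820	C
tae_40	UGAUAAGUAUUUUCGGACGGA	21	UCCGUCCGGAAAUACUUGUCA	BJ276292	C
tae_41	UGCAGUGGCAUAUGCAACUCU	21	AGAGCUGCAUUUGCACCUGCA	GH730467	C
tae_42	UGGCGAGGGACAUACACUGU	20	UACAGUUUAUGUCCCCGGCAG	GH730467	C
tae_43	UUCCGAAAAGCUUGAAGCAAAU	22	UAGCUUCAAGCCUUGAGGAAUA	TC435172	T
tae_44	UUCCGAAAGGCUUGAAGCAAAU	22	UAGCUUCAAGCCUUGAGGAAUA	CA647790	C
tae_45	UUCCGAAAGGCUUGAAGCGAAU	22	UAGCUUCAAGCCUUGAGGAAUA	DR735126	C
tae_46	UUCGAUCGUAAUCGGAUGGUC	21	GGAUGAUCCGGACACGACGGU	CA678208	C
tae_47	UUCUGAAAGGCUUGAAGCAAAU	22	UAGCUUCAAGCCUUGAGGAAUA	CD921947	C
tae_48	UUGUCUUAGAUUCGUCUAGAUA	22	UAUUUAGACAAAUCUAAGACA	TC439689	C
tae_49	UUUCGAAAGGCUUGAAGCAAAU	22	UAGCUUCAAGCCUUGAGGAAUA	TC427740	C
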