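read_name	mirbase_name	sequence	length	abundance	star_name	star_sequence	star_length	star_abundance	confidence
GPB235		AUAAAACCUUCAGCUAUCCAUC	22	4601	GPB7393	UUUGAUAUGUAAGUGGAUAGUU	22	431	***
GPB125	miR5048	UAUUUGCAGGUUUUAGGUCUAA	22	12068	GPB971	AGACCUAGACAUGCAAGUAUA	21	1201	***
GPB1131	miR5049	UCCUAAAUACUUGUUGUUGGG	21	803	GPB31055	AACAACAAGUAUUAUGGUACA	21	16	***
P51WP1692	miR408b	CAGGGAUGGAGCAGAGCAAGG	21	225	P51WP9508	UGCACUGCCUCUUCCCUGGC	20	48	***
GPB8582	miR5050	UUGAGGUCGUUCAACCAGCAA	21	78	P45NP15695	CAGCACUAGCAAGUUGGUCGACCU	24	34	***
GPB86	miR5071	UCAAGCAUCAUAUCAUGGACC	21	19176					**
GPA5819	miR5072	CGUUCCCCAGCGGAGUCGCCA	21	147					**
GPB2903	miR5054	UCCCCACGGACGGCGCCA	18	352					**
GPA3884	miR5055	UCUCGCUACUGAGCUCGGCAU	21	157					**
P45NP9164	miR5056	AGGAAGAACCGGUAAUAAGCA	21	72					**
P45NP15764	miR5073	GUUUGGUGAAUCGGAAACAAUUU	23	28					**
GPB4154	miR5057	AAAUUUCAGAUCAUUUGGACA	21	178					**
TF6215B7984	miR5058	AAUAGUUGAGGGAUGGAAAACA	22	68					**
TF6215B74145	miR5086	ACAUUGGUGGAAGGCGUGGUA	21	20					**
TF6215B6553	miR5074	GAAGGCCACCGUCGGCACCGC	21	142					**
P51WP57134	miR5059	CGUGCCUGGGCAGCACCACCA	21	16					**
P51WP4847	miR5075	UUCUCCGUCGACGCCAUCCGC	21	205					**
P51WP10727	miR5060	CGGCAAGCUAGAGACCGCCAC	21	68					**
P45NP51144	miR5061	UCUGUUCUGUUCUGAUCGGUA	21	24					**
P45NP40836	miR5051	UUUGGCACCUUGAAACUGGGA	21	21					**
P45NP31207	miR5076	UAAAUGGGAGCAGAGCAGGUUU	22	16					**
P45NP21816		UGAGCUACAAAAGGAUUCGUU	21	25					**
P45NP16270	miR1878	AUUUGUAGUGUUCGGAUUGAGUUU	24	33					**
GPB49459	miR5084	AUACAGUACUGCAGAGGAUCCUAA	24	16					**
GPB41819	miR5085	AAGGACAUUUUUUGUGGCAUG	21	47					**
GPB2977	miR5062a	UGAACCUUGGGGAAAAGCCGCAU	23	99					**
GPB5902	miR5062b	UGAACCUUAGGGAACAGCCGCAU	23	57					**
GPB16764	miR5063	UCCACUGGAAGAGGCUUUUGCU	22	54					**
P51WP18432	miR5052	ACCGGCUGGACGGUAGGCAUA	21	36					*
GPB1614	miR5064	UGAAUUUGUCCAUAGCAUCAG	21	513					*
GPB25359	miR5065	UAGGCAAUUCACAUAUACACU	21	27					*
GPB17570	miR5066	AAGUGUAUAUGUGGAUUGCCU	21	73					*
GPB26526	miR5053	CGCAGCUGUAGUCGCCGGCGU	21	22					*
GPB320	miR5077	GUUUCACGUCGGGUUCACCA	20	5056					*
P45NP187203	miR5078	GGUCGUUCGACCGCGGCAUUU	21	25					*
GPB373	miR5067	UGAGCGACAAGUAAUAUGGAU	21	4043					*
P45NP20958	miR5068	AUCAGGUAGAUCGGGUAUGGGUAU	24	40					*
P45NP15484	miR5079	UUUGGAUUUGUUAUUUUGGUAU	22	68					*
GPB9781	miR5080	AAAAAGAUCAUACCGUGAGAG	21	88					*
GPB37150	miR5069	UAGGUGAUUGAUUUGACUAAC	21	17					*
GPA47901	miR5081	UAAUUUGUAGCAAAUUGGUGU	21	16					*
GPA42571	miR5082	CGCGAUGAUGGCCGCGCGGGCUCA	24	17					*
GPA18850	miR5083	AGACUACAAUUAUCUGAUCA	20	28					*
GPA14470	miR5070	AACUAAGUAUGGUCGGAGGGU	21	49					*
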