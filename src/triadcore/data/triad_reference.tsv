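id	taxa	species	source	superposed_percent	rmsd	d_dh	d_hs	d_sd
1AZW	Bacteria	Xanthomonas campestris	experimental	10.20	1.330	4.4	7.8	10.5
2BKL	Bacteria	Myxococcus xanthus	experimental	27.60	0.726	4.6	8.3	10.6
1A88	Bacteria	Streptomyces lividans	experimental	12.30	1.080	4.6	7.9	10.6
1VE7	Archaea	Aeropyrum pernix	experimental	15.76	1.083	4.7	8.4	10.4
1MU0	Archaea	Thermoplasma acidophilum	experimental	17.00	1.013	4.3	7.8	10.1
1AC5	Fungi	Saccharomyces cerevisiae	experimental	17.86	1.441	4.8	7.7	10.8
1WPX	Fungi	Saccharomyces cerevisiae	experimental	12.30	1.168	4.6	7.4	10.4
1N1M	Animalia	Homo sapiens	experimental	16.29	1.163	4.8	7.7	10.7
1QFS	Animalia	Sus scrofa	experimental	100	0.000	4.6	8.1	10.5
1ORW	Animalia	Sus scrofa	experimental	18.29	1.092	4.8	7.7	10.7
2BUC	Animalia	Sus scrofa	experimental	17.15	1.108	4.8	7.7	10.7
PM0078228	Plantae	Arabidopsis thaliana	predicted	16.7	1.021	4.5	8.2	11.2
PM0078229	Protozoa	Plasmodium falciparum	predicted	69.3	0.686	4.6	8.1	10.5
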