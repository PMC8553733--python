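# source: region-specific average Ae for the 6 loci ranking in the top 20 of every region
name	Africa, Sub-Sahara	N Africa, SW Asia, Europe	South Central Asia	East Asia	Oceania	Americas
mh01KK-212	10.35	9.26	9.03	11.88	9.29	5.98
mh02KK-014	14.06	8.00	7.93	7.89	6.88	5.79
mh05KK-170	9.16	9.53	11.60	9.33	7.23	9.81
mh12KK-201	11.28	7.76	7.94	8.11	6.13	7.07
mh13KK-218	7.61	7.95	8.35	7.79	4.33	8.84
mh16KK-259	6.87	6.52	7.49	10.24	9.75	8.35
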