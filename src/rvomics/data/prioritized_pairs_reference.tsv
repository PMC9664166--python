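# Curated reference table: 15 prioritized protein:transcript pairs from the
# monocrotaline rat right-ventricle model (protein q < 0.05 and |z| >= 1.96;
# transcript FDR < 0.05 and linear fold change > 1.5), with fold changes
# reported for the same genes by independent PAH studies:
#   fischer_suhx_fc, sd_suhx_fc  — microarray, Fischer / Sprague-Dawley rats
#                                  with SU5416 + hypoxia; linear-ratio convention
#   mct_sd_fc, suhx_sd_fc        — RNA-seq, Sprague-Dawley rats with MCT /
#                                  SU5416 + hypoxia; signed-fold convention
# Missing entries are kept verbatim as printed ("—", "-", blank).
description	symbol	protein_z	protein_log2fc	protein_q	transcript_log2fc	transcript_p	fischer_suhx_fc	sd_suhx_fc	mct_sd_fc	suhx_sd_fc
natriuretic peptide A	Nppa	7.55	8.52	6.73E-07	4.19	1.55E-04	47.56	-	—	—
thrombospondin 4	Thbs4	5.56	6.38	8.00E-06	4.4	2.80E-07	16.51	10.11	1.8	1.3
periostin	Postn	3.83	4.5	1.99E-05	4.56	1.67E-17	8.84	7.06	2.12	1.18
latent transforming growth factor beta binding protein 2	Ltbp2	2.67	3.25	6.17E-03	4.16	3.72E-16	7.5	6.18	1.75	1.22
heme oxygenase 1	Hmox1	4.59	5.33	2.45E-06	2.05	1.67E-17	3.54	—	1.86	1.25
TSC22 domain family, member 1	Tsc22d1	3.82	4.5	1.12E-03	2.1	1.82E-11	2.77	2.59	1.62	1.04
glycoprotein nmb	Gpnmb	3.21	3.83	2.24E-04	2.35	8.47E-08	2.55	—	2.22	1.26
ATPase Na+/K+ transporting subunit alpha 2	Atp1a2	-3.47	-3.38	7.10E-06	-2.23	1.25E-04	0.37	0.32	−1.66	—
glutathione S-transferase zeta 1	Gstz1	-1.97	-1.76	1.18E-03	-2.38	9.02E-23	0.34	-	−1.41	—
collagen type XVIII alpha 1 chain	Col18a1	2.59	3.17	1.02E-05	1.61	8.08E-13	-	-	3.22	—
cysteine and glycine-rich protein 2	Csrp2	3.1	3.72	1.08E-02	2.02	3.69E-05	-	-	1.81	2.09
S100 calcium-binding protein A4	S100a4	2.43	2.99	1.11E-04	1.93	1.55E-04	-	-	1.68	1.04
ankyrin repeat domain 2	Ankrd2	4.04	4.74	3.28E-06	2.49	1.27E-02	-	-	1.61	—
procollagen lysine, 2-oxoglutarate 5-dioxygenase 2	Plod2	6.89	7.82	6.73E-07	2.3	3.43E-15	-	3.36	1.91	1.19
tenascin C	Tnc	5.18	5.96	7.37E-03	2.53	3.08E-07	-	-	1.91
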