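intervention	baseline_coverage	lives_saved_neonatal	lives_saved_1to59m
Full supportive care for prematurity	0.0	5435	0
Artemisinin compounds for treatment of malaria (ACT)	26.2	0	4925
Full supportive care for neonatal sepsis/pneumonia	0.0	3002	0
Assisted vaginal delivery	18.5	2163	0
Oral rehydration solution (ORS)	48.6	64	2056
Kangaroo mother care (KMC)	0.0	2010	0
Oral antibiotics for pneumonia	52.6	0	1805
Neonatal resuscitation	40.2	1582	0
Injectable antibiotics for neonatal sepsis	73.1	1382	0
Prevention of mother-to-child transmission of HIV (including breastfeeding choices) (PMTCT)	23.3	0	1020
Households protected from malaria (ITN/IRS)	70.9	0	999
Multiple micronutrient supplementation in pregnancy	0.0	871	18
Treatment for moderate acute malnutrition (MAM)	0.0	0	849
Point-of-use filtered water	0.8	22	781
Zinc supplementation	0.0	0	785
Zinc for the treatment of diarrhoea	7.4	20	642
Oral antibiotics for neonatal sepsis	0.0	655	0
Cesarean delivery	76.4	653	0
Breastfeeding promotion	50.0	93	511
Clean cord care	69.7	515	0
Piped water	35.3	14	497
Cotrimoxazole	4.1	0	485
Clean birth environment	59.9	454	0
Basic sanitation	16.5	12	437
Thermal protection	72.2	398	0
Immediate drying and additional stimulation	66.9	360	0
Vitamin A supplementation	23.0	0	304
Treatment for severe acute malnutrition (SAM)	2.7	0	289
Antibiotics for preterm or prolonged premature rupture of the membranes (PROM)	54.7	265	0
Parenteral administration of antibiotics	54.7	265	0
Antibiotics for treatment of dysentery	42.4	7	239
Prevention of malaria in pregnancy	67.5	223	15
Antiretroviral therapy (ART)	22.7	0	236
Appropriate complementary feeding	24.4	0	219
Syphilis detection and treatment	24.0	219	0
Folic acid fortification	0.0	207	0
Calcium supplementation	0.0	186	1
Handwashing with soap	40.9	4	128
Balanced energy supplementation	0.0	61	2
Vitamin A for treatment of measles	23.0	0	32
Tetanus toxoid vaccination (TT)	88.0	21	0
Measles vaccine	92.0	0	2
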