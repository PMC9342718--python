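section	intervention	coverage_increase	lives_saved	share
pregnancy	Tetanus toxoid vaccination (TT)	14.0	669	0.6
pregnancy	Prevention of malaria in pregnancy	56.3	1896	1.7
pregnancy	Syphilis detection and treatment	1.1	15	0.0
pregnancy	Prevention of mother-to-child transmission of HIV (including breastfeeding choices) (PMTCT)	100.0	1450	1.3
pregnancy	Maternal age and birth order	NA	2	0.0
childbirth	Clean birth environment	35.2	1850	1.7
childbirth	Immediate drying and additional stimulation	39.3	2078	1.9
childbirth	Thermal protection	42.4	3026	2.8
childbirth	Clean cord care	40.9	3041	2.8
childbirth	Antibiotics for preterm or prolonged premature rupture of the membranes (PROM)	32.1	836	0.8
childbirth	Parenteral administration of antibiotics	32.1	836	0.8
childbirth	Assisted vaginal delivery	10.8	1104	1.0
childbirth	Neonatal resuscitation	23.6	2511	2.3
childbirth	Parenteral administration of uterotonics	38.3	0	0.0
childbirth	Cesarean delivery	51.7	7134	6.6
breastfeeding	Age-appropriate breastfeeding practices	50.0	7935	7.3
preventive	Vitamin A supplementation	76.0	1247	1.2
preventive	Basic sanitation	87.3	1992	1.8
preventive	Point-of-use filtered water	99.1	5560	5.1
preventive	Piped water	60.6	2140	2.0
preventive	Handwashing with soap	100.0	387	0.4
preventive	Hygienic disposal of children's stools	57.6	0	0.0
preventive	Households protected from malaria (ITN/IRS)	58.3	12906	11.9
preventive	Complementary feeding (via reduction in stunting)	57.5	1361	1.3
preventive	Complementary feeding (via reduction in wasting)	57.5	464	0.4
vaccines	DPT vaccine	12.0	882	0.8
vaccines	Haemophilus influenzae b vaccine	12.0	222	0.2
vaccines	Pneumococcal vaccine (3 doses)	100.0	3433	3.2
vaccines	Rotavirus vaccine (3 doses)	100.0	416	0.4
vaccines	Measles vaccine (1 dose)	10.2	970	0.9
curative	Case management of neonatal sepsis/pneumonia	16.0	3617	3.3
curative	Oral rehydration solution (ORS)	55.5	4911	4.5
curative	Antibiotics for treatment of dysentery	53.6	540	0.5
curative	Zinc for the treatment of diarrhea	98.2	1438	1.3
curative	Oral antibiotics for pneumonia	49.3	9173	8.5
curative	Vitamin A for treatment of measles	76.0	237	0.2
curative	Artemisinin compounds for the treatment of malaria (ACT)	88.7	21204	19.6
curative	Treatment for severe acute malnutrition (SAM)	100.0	830	0.8
curative	Cotrimoxazole	97.3	31	0.0
curative	Antiretroviral therapy (ART)	92.6	46	0.0
total	Total	NA	108390	100
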