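section	intervention	baseline_coverage	endline_coverage	change_printed	lives_saved_intervention	share_intervention	lives_saved_direct	share_direct
pregnancy	Tetanus toxoid vaccination (TT)	86.0	88.0	2.0	95	0.3	95	0.2
pregnancy	Prevention of malaria in pregnancy	43.7	67.5	23.8	810	2.3	777	1.6
pregnancy	Syphilis detection and treatment	23.6	24.0	0.4	4	0.0	4	0.0
pregnancy	Prevention of mother-to-child transmission of HIV (including breastfeeding choices) (PMTCT)	0.0	23.3	23.3	1445	4.2	1446	3.0
pregnancy	Maternal age and birth order	NA	NA	NA	2	0.0	2	0.0
childbirth	Clean birth environment	46.8	59.9	13.1	736	2.1	736	1.5
childbirth	Immediate drying and additional stimulation	52.3	66.9	14.6	809	2.3	808	1.7
childbirth	Thermal protection	56.5	72.2	15.8	1205	3.5	1205	2.5
childbirth	Clean cord care	54.5	69.7	15.2	1318	3.8	1318	2.7
childbirth	Antibiotics for preterm or prolonged premature rupture of the membranes (PROM)	42.7	54.7	11.9	320	0.9	320	0.7
childbirth	Parenteral administration of antibiotics	42.7	54.7	11.9	320	0.9	320	0.7
childbirth	Assisted vaginal delivery	14.4	18.5	4.0	439	1.3	439	0.9
childbirth	Neonatal resuscitation	31.4	40.2	8.8	988	2.9	988	2.1
childbirth	Caesarean delivery	48.3	76.4	28.1	4145	12.0	4145	8.6
breastfeeding	Age-appropriate breastfeeding practices	60.6	50.0	-10.6	-1711	-5.0	-1786	-3.7
preventive	Change in stunting prevalence	27.5	18.8	8.7	NA	NA	4315	9.0
preventive	Vitamin A supplementation (2 doses)	24.0	23.0	-1.0	-21	-0.1	-21	0.0
preventive	Basic sanitation	12.7	16.5	3.8	120	0.3	115	0.2
preventive	Point-of-use filtered water	0.9	0.8	-0.1	-7	0.0	-7	0.0
preventive	Piped water	39.4	35.3	-4.2	-191	-0.6	-190	-0.4
preventive	Handwashing with soap	0.0	40.9	40.9	249	0.7	234	0.5
preventive	Insecticide-treated net/indoor residual spraying (ITN/IRS)	41.7	70.9	29.2	6433	18.7	6437	13.4
preventive	Complementary feeding(via reduction in stunting)	42.5	24.4	-18.1	394	1.1	NA	NA
preventive	Complementary feeding(via reduction in wasting)	42.5	24.4	-18.0	428	1.2	NA	NA
vaccines	Diphtheria, pertussis, and tetanus (DPT) vaccine	88.0	98.0	10.8	869	2.5	870	1.8
vaccines	Haemophilus influenzae type B	88.0	98.0	10.8	244	0.7	243	0.5
vaccines	Pneumococcal vaccine (3 doses)	0.0	99.0	99.0	3931	11.4	3938	8.2
vaccines	Rotavirus vaccine (3 doses)	0.0	98.0	98.0	655	1.9	669	1.4
vaccines	Measles vaccine (1 dose)	89.8	92.0	5.4	239	0.7	226	0.5
curative	Case management of neonatal sepsis/pneumonia	57.1	73.1	16.0	4271	12.4	4271	8.9
curative	Oral rehydration salts (ORS)	44.5	48.6	4.1	985	2.9	917	1.9
curative	Antibiotics for treatment of dysentery	46.4	42.2	-4.0	-116	-0.3	-118	-0.2
curative	Zinc for treatment of diarrhoea	1.8	7.4	5.6	223	0.6	208	0.4
curative	Oral antibiotics for pneumonia	50.7	52.6	1.9	422	1.2	396	0.8
curative	Vitamin A for treatment of measles	24.0	23.0	-1.0	-9	0.0	-9	0.0
curative	Artemisinin-based combination therapy (ACTs) (within 48hours)	11.3	26.2	14.9	4322	12.5	4325	9.0
curative	Treatment for severe acute malnutrition (SAM)	0.0	2.7	2.7	37	0.1	0	0.0
curative	Change in wasting prevalence	8.6	4.7	3.9	NA	NA	10372	21.6
curative	Cotrimoxazole	2.7	4.1	1.4	31	0.1	31	0.1
curative	ART for children	7.4	22.7	15.2	43	0.1	45	0.1
total	Total	NA	NA	NA	34477	100	48084	100
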