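gene	fc_tolerant	fc_susceptible	log2fc_tolerant	log2fc_susceptible	family	published_trait	published_group
TraesCS4D02G298600	6.29	0.51	2.62	-1.20	TaERF	highly heat-tolerant	1
TraesCS5D02G317100	5.94	0.74	1.84	-0.52	TaDREB	moderately highly heat-tolerant	1
TraesCS1A02G221900	2.11	0.58	1.08	-0.78	TaDREB	moderately highly heat-tolerant	1
TraesCS2D02G515900	4.03	1.21	1.86	0.15	TaDREB	heat-tolerant	2
TraesCS5A02G468800	3.81	1.23	1.41	0.27	TaERF	heat-tolerant	2
TraesCS6B02G375400	4.34	1.27	1.34	0.18	TaERF	heat-tolerant	2
TraesCS1A02G058400	1.05	0.22	0.07	-2.42	TaAP2	heat-tolerant	1
TraesCS5B02G214400	1.09	0.42	-0.25	-1.29	TaERF	heat-tolerant	4
TraesCS4B02G268100	0.65	4.60	-1.02	2.20	TaDREB	highly heat-susceptible	3
TraesCS5B02G193200	0.44	3.33	-2.08	1.71	TaDREB	highly heat-susceptible	3
TraesCS3B02G293000	0.50	2.18	-1.02	0.94	TaRAV	moderately highly heat-susceptible	3
TraesCS5A02G215900	0.52	5.44	-1.79	0.74	TaERF	moderately highly heat-susceptible	3
TraesCS6B02G331000	1.69	6.72	0.04	2.74	TaDREB	heat-susceptible	2
TraesCS1B02G235100	1.83	2.36	0.86	1.23	TaDREB	heat-susceptible	2
TraesCS2B02G448100	1.61	2.86	0.26	1.01	TaERF	heat-susceptible	2
TraesCS2D02G425700	3.93	2.51	1.91	1.20	TaERF	neutral	2
TraesCS2D02G515800	9.98	3.17	1.79	1.56	TaAP2	neutral	2
TraesCS4B02G299600	0.54	0.41	-1.15	-1.45	TaERF	neutral	4
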