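name	sd	se	n
Net_Outcome	386.00	70.47	30
Bet50_Prv1Loss	14.75	2.69	30
Bet10_Prv1Loss	16.05	2.93	30
Bet50_Prv2Loss	8.63	1.58	30
Bet10_Prv2Loss	8.98	1.64	30
Bet50_Prv3Loss	5.17	0.94	30
Bet10_Prv3Loss	5.85	1.07	30
Bet50_Prv2NetLoss	16.21	2.96	30
Bet10_Prv2NetLoss	18.00	3.29	30
Bet50_Prv3NetLoss	13.66	2.49	30
Bet10_Prv3NetLoss	12.55	2.29	30
BIS_NP	4.61	0.84	30
BIS_MI	3.28	0.60	30
BIS_AI	3.19	0.58	30
BIS_Tot	8.60	1.57	30
Cluster01	63.99	11.68	30
Cluster02	62.27	11.37	30
Cluster03	120.22	21.95	30
Cluster04	64.65	11.80	30
Cluster05	77.14	14.08	30
Cluster06	66.63	12.16	30
Cluster07	81.01	14.79	30
Cluster08	100.90	18.42	30
Cluster09	97.02	17.71	30
Cluster10	109.55	20.00	30
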