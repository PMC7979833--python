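id	origin	subfamily	motif	lambda_base	expected_gain	observed_lambda
WP_094550238.1	Rubricoccus marinus	BacHR	TSA	537	40.7	541
WP_095509924.1	Rubrivirga marina	BacHR	TSA	537	39.8	548
WP_095512583.1	Rubrivirga marina	BacHR	TTD	537	35.5	577
WP_082380780.1	Bacillus sp. CHD6a	XeR	DTA	565	35.3	566
WP_063559373.1	Bacillus horikoshii	XeR	DTA	565	35.3	565
WP_012628826.1	Cyanothece sp. PCC 7425	BacHR	TSV	537	32.9	566
OWY65757.1	Cyanobacterium TDX16	BacHR	TSD	537	32.9	546
WP_052056058.1	Myxosarcina sp. GI1	BacHR	TTV	537	31.2	557
PSG98511.1	Nanohaloarchaea archaeon SW 7 43 1	XeR	DSA	565	29.2	572
SAMEA2621839_1737175_2	Metagenome sequence	ClR	NTQ	530	25.7	520
SAMEA2620666_5055_4	Metagenome sequence	ClR	NTQ	530	25.1	525
AIG86802.2	Nonlabens sp. YIK11	PR	DTE	520	21.5	531
SAMEA2622673_750013_58	Metagenome sequence	ClR	NTQ	530	21.4	534
EBN24473.1	Metagenome sequence	PR	DTE	520	20.0	525
SAMEA2620404_88891_6	Metagenome sequence	PR	DTE	520	20.0	527
WP_051881578.1	Parvularcula oceani	NaR	NDQ	525	19.7	534
WP_084709429.1	Rubrobacter aplysinae	DTG	DTG	535	19.5	541
SAMEA2619531_1917517_3	Metagenome sequence	PR	DTE	520	18.0	537
SAMEA2622766_213679_12	Metagenome sequence	XeR	DSA	565	17.8	572
WP_100255947.1	Reinekea forsetii	PR	DTE	520	17.1	524
PSR14004.1	Bacteroidetes bacterium	PR	DTE	520	15.4	537
SAMEA2620980_19116_14	Metagenome sequence	PR	DTE	520	15.4	536
KIF37192.1	Hassallia byssoidea VB512170	BacHR	TSD	537	15.1	535
WP_047006274.1	Erythrobacter gangjinensis	NaR	NDQ	525	13.7	531
WP_104913209.1	Pontimonas salivibrio	PR	DTE	520	12.2	538
PSO50292.1	Cyanobacteria bacterium QH 1 48 107	CyanDTEDTD	DTD	545	12.0	548
WP_022671827.1	Sphingopyxis baekryungensis	ClR	NTQ	530	11.0	518
KRP08428.1	Sphingobacteriales bacterium BACL12 MAG120802bin5	PR	DTE	520	10.9	531
SAMEA2621401_1198262_5	Metagenome sequence	PR	DTE	520	10.9	534
WP_106137740.1	Spirosoma oryzae	NaR	NDQ	525	10.8	533
WP_045053084.1	Aliterella atlantica	BacHR	TSD	537	10.8	533
WP_092678153.1	Rosenbergiella nectarea	DTG	DTG	535	10.8	533
SAMEA2620980_1827033_1	Metagenome sequence	PR	DTE	520	10.4	537
PWL28924.1	Fluviicola sp. XM24bin1	PR	DTE	520	10.4	538
SAMEA2622173_654706_7	Metagenome sequence	PR	DTE	520	10.4	530
SAMEA2619399_1397592_7	Metagenome sequence	PR	DTE	520	10.4	529
WP_055875688.1	Sphingomonas sp. Leaf34	DTG	DTG	535	10.3	540
WP_056475157.1	Sphingomonas sp. Leaf38	DTG	DTG	535	10.3	540
ECV93033.1	Metagenome sequence	PR	DTE	520	10.3	542
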