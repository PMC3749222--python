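macro_area	population	label	count	anomaly
Asia	Mongolia	Q1a1-M120	3
Asia	Mongolia	Q1a2-M25	3
Asia	Mongolia	Q1a3a-L53*	1
Asia	Mongolia	Q1a3a1c-L330	15
Asia	Kamchatka	Q1a-MEH2*	3
Asia	Kamchatka	Q1a3a1a-M3*	2
Mexico	Mexico	Q1a3a1-L54*	48
Mexico	Mexico	Q1a3a1a-M3*	122
Mexico	Mexico	Q1a3a1a-M3*	1	duplicated:DYS390
Mexico	Mexico	Q1a3a1b-L191	8
Mexico	Mexico	Q1a3a1f-PV3	1	microvariant:DYS19=13.2
Mexico	Mexico	Q1a3a1g-PV4	1
Central America	C American Isthmus	Q1a3a1a-M3*	3
Central America	Nicaragua	Q1a3a1-L54*	2
Central America	Costa Rica	Q1a3a1a-M3*	1
Central America	Panama	Q1a3a1-L54*	2
Central America	Panama	Q1a3a1a-M3*	34
Central America	Panama	Q1b-M378	1
Andean Regions	NS America	Q1a3a1-L54*	2
Andean Regions	NS America	Q1a3a1a-M3*	6
Andean Regions	NS America	Q1b-M378	1
Andean Regions	Peru	Q1a3a1-L54*	17
Andean Regions	Peru	Q1a3a1a-M3*	126
Andean Regions	Peru	Q1a3a1a2-M194	1
Andean Regions	Peru	Q1a3a1a4-SA01	5
Andean Regions	Peru	Q1a3a1a4-SA01	1	microvariant:DYS391=10.2
Andean Regions	Peru	Q1a3a1a5-M557	7
Andean Regions	Peru	Q1a3a1b-L191	1
Andean Regions	Peru	Q1a3a1a6-PV2	1
Andean Regions	Bolivia	Q1a3a1-L54*	1
Andean Regions	Bolivia	Q1a3a1a-M3*	8
Andean Regions	Chile	Q1a3a1a-M3*	20
South East America	Brazil	Q1a3a1a-M3*	7
South East America	SS America	Q1a3a1-L54*	1
South East America	SS America	Q1a3a1a-M3*	6
South East America	Uruguay	Q1a3a1a-M3*	1
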