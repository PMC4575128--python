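locus	class	Tm	PIC	Rp	Na	Ne	I	He
PLC5	EST	60	0.45	2	2	1.81	0.64	0.45
PLC10	EST	59	0.55	1.35	2	1.76	0.62	0.43
PLC16	EST	59	0.05	2.02	3	1.06	0.15	0.06
PLC17	EST	59	0.48	1.7	2	1.64	0.58	0.39
PLC21	EST	59	0.37	2	2	1.59	0.56	0.37
PLC22	EST	60	0.56	2.51	4	2.46	1	0.6
PLC30	EST	61	0.4	2.02	3	1.68	0.7	0.41
PLC35	EST	60	0.27	1.98	3	1.36	0.49	0.26
PLC38	EST	59	0.37	2	2	1.59	0.56	0.37
PLC40	EST	60	0.35	2.02	2	1.57	0.55	0.37
PLC42	EST	60	0.55	2	3	2.22	0.87	0.55
PLC46	EST	59	0.48	2	2	1.92	0.67	0.48
PLC51	EST	62	0.23	1.95	2	1.29	0.38	0.22
PLC60	EST	60	0.45	1.35	4	1.2	0.4	0.16
PLC64	EST	61	0.49	2.09	3	2.04	0.83	0.51
PLC66	EST	60	0.07	2.02	2	1.08	0.17	0.08
PLC70	EST	60	0.22	2.19	2	1.46	0.5	0.32
PLC74	EST	61	0.45	2.09	2	2	0.69	0.5
PLC80	EST	58	0.06	2.05	2	1.02	0.06	0.02
PLC81	EST	60	0.56	2	3	2.27	0.91	0.56
PLC88	EST	59	0.39	2.02	3	1.63	0.69	0.39
PLC95	EST	59	0.48	1.95	3	1.89	0.78	0.47
PBALC13	EST	60	0.32	2.19	4	1.5	0.7	0.34
PBALC18	EST	60	0.56	2.14	3	2.53	1	0.61
PBALC24	EST	60	0.4	2	3	1.66	0.72	0.4
PBALC29	EST	60	0.49	1.93	3	1.85	0.74	0.46
PBALC224	EST	60	0.63	1.95	3	1.44	0.58	0.3
PBALC250	EST	60	0.39	1.98	2	1.23	0.34	0.19
PBALC0260	EST	60	0.3	2	3	1.67	0.69	0.4
PBALC0347	EST	59	0.38	2.07	3	2.64	1.03	0.62
PBALC0353	EST	59	0.19	2	3	1.58	0.68	0.37
GLLC106	genomic	56	0.59	2.12	3	1.67	0.7	0.4
GLLC108	genomic	56	0.69	1.93	3	1.31	0.46	0.24
GLLC511	genomic	56	0.62	1.98	4	2.35	1.04	0.58
GLLC527	genomic	56	0.6	2.05	3	1.52	0.64	0.35
GLLC538	genomic	56	0.77	2.21	3	2.33	0.93	0.57
GLLC541	genomic	56	0.52	2.23	2	1.64	0.58	0.39
GLLC563	genomic	56	0.48	2.14	5	4.81	1.59	0.8
GLLC598	genomic	55	0.68	2.19	4	3.25	1.26	0.7
GLLC609	genomic	55	0.41	1.95	3	2.04	0.83	0.51
GLLC614	genomic	55	0.52	1.98	3	2.01	0.74	0.51
SSR124	genomic	52	0.69	1.93	3	2.95	1.09	0.66
SSR154	genomic	51	0.41	1.95	3	1.69	0.72	0.41
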