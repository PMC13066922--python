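sample_id	t01	t02	t03	t04	t05	t06	t07	t08	t09	t10	t11	t12
s01	3937	3	2	0	100	3937	0	20	1	0	0	0
s02	3943	3	2	0	100	3944	0	20	1	0	0	0
s03	4000	3	2	0	0	4000	0	20	1	0	0	0
s04	4016	3	2	0	0	4017	0	0	1	0	0	0
s05	3823	3	2	400	0	3823	0	0	1	0	0	0
s06	4005	3	2	0	0	4005	49	0	1	0	0	0
s07	1536	3	2	0	0	1536	0	0	1	5000	0	0
s08	4029	3	2	0	0	4030	0	0	1	0	26	0
s09	4036	3	2	0	0	4036	0	0	1	0	26	0
s10	4056	2	2	0	0	4056	0	0	1	0	0	0
s11	4062	2	2	0	0	4063	0	0	1	0	0	0
s12	4069	2	2	0	0	4069	0	0	1	0	0	0
s13	4075	2	2	0	0	4076	0	0	1	0	0	0
s14	4082	2	2	0	0	4082	0	0	1	0	0	0
s15	4088	2	2	0	0	4089	0	0	1	0	0	0
s16	4095	2	2	0	0	4095	0	0	1	0	0	0
s17	4101	2	2	0	0	4102	0	0	1	0	0	0
s18	4108	2	2	0	0	4108	0	0	1	0	0	0
s19	4114	2	2	0	0	4115	0	0	1	0	0	0
s20	4121	2	2	0	0	4121	0	0	1	0	0	0
s21	4128	0	2	0	0	4129	0	0	1	0	0	0
s22	4135	0	2	0	0	4135	0	0	1	0	0	0
s23	4141	0	2	0	0	4142	0	0	1	0	0	0
s24	4148	0	2	0	0	4148	0	0	1	0	0	0
s25	4154	0	2	0	0	4155	0	0	1	0	0	0
s26	4162	0	0	0	0	4162	0	0	1	0	0	0
s27	4168	0	0	0	0	4169	0	0	1	0	0	0
s28	4175	0	0	0	0	4175	0	0	1	0	0	0
s29	4181	0	0	0	0	4182	0	0	1	0	0	0
s30	4188	0	0	0	0	4188	0	0	1	0	0	0
s31	4195	0	0	0	0	4195	0	0	0	0	0	0
s32	4201	0	0	0	0	4202	0	0	0	0	0	0
s33	4208	0	0	0	0	4208	0	0	0	0	0	0
s34	4214	0	0	0	0	4215	0	0	0	0	0	0
s35	4221	0	0	0	0	4221	0	0	0	0	0	0
s36	4227	0	0	0	0	4228	0	0	0	0	0	0
s37	4234	0	0	0	0	4234	0	0	0	0	0	0
s38	4000	0	0	0	0	4000	0	0	0	0	0	0
s39	3999	0	0	0	0	4000	0	0	0	0	0	0
s40	250	0	0	0	0	250	0	0	0	0	0	0
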