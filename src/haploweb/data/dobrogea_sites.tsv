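town	location	latitude	longitude	date	temp_c	ec_us_cm	eh_mv	h2s_um	h2s_inferred	species
Hagieni	Hagieni Spring	43°48'08.90"N	28°28'29.00"E	09.2012	18.1	1080	-245	172	yes	N. hrabei;P. ruffoi
Mangalia	Movile Cave	43°49'36.38"N	28°33'43.48"E	09.2011	21.2	1071	-341	245	no	N. cf. stygius;P. racovitzai
Mangalia	str. Matei Basarab 62	43°49'09.11"N	28°34'16.10"E	09.2012	19.8	1380	-266	188	yes	N. cf. stygius;N. decui
Mangalia	str. Matei Basarab 74	43°49'10.61"N	28°34'07.90"E	09.2012	18.1	1460	-174	126	yes	N. decui
Mangalia	str. Gheorge Netoi 1	43°49'10.87"N	28°34'12.74"E	09.2011	18.6	1078	-263	133	no	N. cf. stygius
Mangalia	str. Dumitru Ana 13	43°49'23.59"N	28°34'01.45"E	09.2011	19.1	1052	-120	101	no	N. cf. stygius
Mangalia	str. Ion Mecu 51	43°49'25.75"N	28°34'29.40"E	09.2011	19.9	1135	-89	66	no	N. cf. stygius
Mangalia	Aleea Cetatii 1	43°48'53.21"N	28°35'01.84"E	05.2013	19.3	1650	-64	48	yes	N. cf. stygius;P. racovitzai
Mangalia	str. Maior Giurescu 22	43°49'15.43"N	28°34'46.19"E	09.2012	18.4	2440	28	0	yes	N. gallicus
Mangalia	str. Horia Closca Crisan 13	43°49'18.67"N	28°34'23.10"E	09.2012	19.7	1450	40	0	yes	N. decui
Mangalia	str. Delfinului 16	43°48'34.73"N	28°34'44.89"E	09.2011	19.1	1473	66	0	no	N. gallicus
Mangalia	str. Mihai Viteazu 20	43°48'49.30"N	28°34'50.31"E	09.2011	17.4	1193	68	0	no	N. decui
Mangalia	str. Pictor Tonitza 1	43°49'09.05"N	28°35'03.71"E	09.2011	19.0	1242	104	0	no	N. cf. stygius;N. decui;P. racovitzai
Mangalia	str. Vasile Parvan 16	43°48'51.25"N	28°35'07.32"E	09.2012	15.0	2166	139	0	yes	N. gallicus
Mangalia	str. Delfinului 16	43°48'34.73"N	28°34'44.89"E	09.2011	19.1	1473	66	0	no	N. gallicus
Albesti	near road 393	43°47'47.50"N	28°25'35.80"E	09.2011	13.8	1445	72	0	no	N. decui
Doi Mai	str. Mihail Kogalniceanu 393	43°47'25.72"N	28°34'37.10"E	09.2011	16.1	2235	56	0	no	N. dobrogicus;N. decui
Dulcesti	near road 394	43°54'00.07"N	28°32'39.10"E	09.2011	15.4	1216	63	0	no	N. gallicus;N. decui
Limanu	corner str. Marului/str. Traian Vuia	43°48'10.01"N	28°31'24.83"E	09.2011	16.2	1092	69	0	no	N. dobrogicus;N. decui
Vama Veche	str. Mihail Kogalniceanu 23	43°45'07.07"N	28°34'18.59"E	05.2013	14.3	1690	55	0	yes	N. dobrogicus
Vama Veche	str. Plajei 100	43°45'09.10"N	28°34'38.40"E	05.2013	14.0	1760	73	0	yes	N. decui
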