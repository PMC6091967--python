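sample	fresh	date	river	system	region	reads	pct_target	otus	shannon
BC0023	yes	27/05/2014	Mondera	Tera	Zamora	187750	85.89	36	0.18
BC0024	yes	19/05/2015	Tuiza	Tuela	Zamora	167956	59.82	8	0.08
BC0028	yes	02/09/2014	Tuiza	Tuela	Zamora	64908	60.71	16	1.22
BC0041	yes	06/11/2013	Curricha	Tuela	Zamora	157264	0.30	5	1.18
BC0061	yes	29/05/2014	Parada	Tera	Zamora	137299	67.90	17	0.27
BC0240	yes	01/09/2014	Arrochas	Tuela	Zamora	123821	8.89	14	1.46
BC0293	yes	01/09/2014	Arrochas	Tuela	Zamora	141171	84.84	36	0.87
BC0648	no	21/07/2014	Yuso	-	León	47626	1.90	6	0.79
BC0780	no	21/07/2014	Lechada	-	León	71798	32.64	10	0.61
BC0834	no	01/09/2014	Arrochas	Tuela	Zamora	104049	73.96	15	1.36
BC0849	no	01/09/2014	Arrochas	Tuela	Zamora	26473	26.51	20	1.46
BC0857	no	11/09/2014	Castro	Tera	Zamora	35716	3.48	8	1.60
BC0861	no	02/09/2014	Tuiza	Tuela	Zamora	151022	7.87	9	0.86
BC0868	yes	20/05/2015	Arrochas	Tuela	Zamora	165393	86.91	24	0.90
BC0873	no	03/09/2014	Tuela	Tuela	Zamora	135386	20.10	8	0.37
BC0877	no	03/09/2014	Tuela	Tuela	Zamora	82208	46.11	14	1.07
BC0899	no	11/09/2014	Castro	Tera	Zamora	111970	59.08	17	0.19
BC0917	no	03/09/2014	Tuela	Tuela	Zamora	144577	76.54	26	0.70
BC0939	no	01/09/2014	Arrochas	Tuela	Zamora	122615	37.39	21	0.22
BC0943	no	02/09/2014	Tuiza	Tuela	Zamora	154772	1.23	5	0.34
BC0974	no	01/09/2014	Arrochas	Tuela	Zamora	77147	51.40	29	0.36
BC0981	no	10/09/2014	Los Tornos	Tera	Zamora	100335	18.25	19	1.14
BC1035	yes	28/05/2014	Cabril	Tera	Zamora	17301	1.88	7	1.76
BC1041	yes	10/06/2015	Tornos	Tera	Zamora	126101	77.50	20	1.31
BC1059	yes	12/06/2015	Parada	Tera	Zamora	184014	80.66	17	0.06
BC1062	yes	14/09/2014	Porto	Tuela	Zamora	124906	0.24	2	0.55
BC1101	yes	04/06/2015	Cabril	Tera	Zamora	213479	86.15	17	0.22
BC1108	yes	09/06/2015	Cabril	Tera	Zamora	138976	73.91	21	0.62
BC1123	yes	15/09/2014	Mondera	Tera	Zamora	219398	88.38	16	0.02
BC1144	yes	15/09/2014	Mondera	Tera	Zamora	52286	72.83	23	0.54
BC1150	yes	16/09/2014	Parada	Tera	Zamora	106664	36.13	17	0.49
BC1154	yes	23/09/2014	Parada	Tera	Zamora	117200	0.40	6	1.27
BC1243	yes	09/06/2015	Cabril	Tera	Zamora	267589	90.10	29	0.14
C1131	no	16/07/2010	Razoncillo	-	Soria	172686	83.91	30	0.81
C1654	no	16/07/2010	Razoncillo	-	Soria	118641	18.79	11	1.16
C1661	no	16/07/2010	Razon	-	Soria	11146	32.54	7	0.87
C1671	no	16/07/2010	Razon	-	Soria	171001	0.12	5	1.28
C1796	no	16/07/2010	Razoncillo	-	Soria	118301	0.12	2	0.57
C3855	no	06/11/2013	Curricha	Tuela	Zamora	112722	2.54	3	0.20
C4323	no	04/10/2014	Romadriu	-	Lleida	9309	1.36	4	1.19
OHGC001	no	27/06/2015	Sil	-	Galicia	121419	49.26	14	0.27
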