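sequence	charge	observed_ms	predicted_ms
AQGHRPQDENPVVHFFK	2	4.24	4.44
AQGHRPQDENPVVHFFK	3	2.26	2.17
FSWGAEGQKPGFGYGGR	2	3.97	3.96
HRDTGILDSLGR	2	2.62	2.74
HRDTGILDSLGR	3	1.26	1.38
YLASASTMDHAR	1	11.4	11.83
YLASASTMDHAR	2	2.8	2.57
GLKGHDAQGTLSK	2	2.44	2.72
TTHYGSLPQK	1	9.48	10.14
TTHYGSLPQK	2	1.9	2.07
FFGSDRGAPK	2	1.99	2.10
DTGILDSLGR	1	8.75	9.02
GHDAQGTLSK	1	8.48	8.69
GHDAQGTLSK	2	1.71	1.86
TPPPSQGK	1	5.51	6.69
LGGRDSR	2	1.26	1.51
FFGSDR	1	5.23	5.41
HGFLPR	1	5.87	5.63
HGFLPR	2	1.53	1.20
SGSPMAR	1	4.69	5.51
NIVTPR	1	5.42	5.36
GLSLSR	1	4.78	4.74
ASDYK	1	3.97	3.94
NTDGSTDYGILQINSR	2	3.34	3.68
WWCNDGRTPGSR	2	2.71	2.92
FESNFNTQATNR	2	2.71	2.71
GYSLGNWVCAAK	1	11.83	11.89
GYSLGNWVCAAK	2	2.62	2.45
GTDVQAWIR	1	8.12	8.96
WWCNDGR	1	7.04	7.67
WWCNDGR	2	1.62	1.57
HGLDNYR	1	6.5	7.01
HGLDNYR	2	1.53	1.49
KVFGR	1	4.24	4.53
KVFGR	2	1.17	0.99
TPGSR	1	3.16	3.76
VFGR	1	3.43	3.39
GCRL	1	3.34	3.44
EPMIGVNQELAYFYPELFR	2	5.05	5.27
FFVAPFPEVFGKEKVNELSK	2	4.87	5.17
FFVAPFPEVFGKEKVNELSK	3	2.08	2.64
HPIKHQGLPQEVLNENLLR	2	5.14	5.09
HPIKHQGLPQEVLNENLLR	3	2.17	2.51
EDVPSERYLGYLEQLLR	2	4.33	4.43
HQGLPQEVLNENLLR	2	3.7	3.67
HQGLPQEVLNENLLR	3	1.81	1.90
FFVAPFPEVFGKEK	2	3.51	3.35
FFVAPFPEVFGK	1	13.54	12.72
HIQKEDVPSER	3	1.44	1.40
YLGYLEQLLR	1	12.55	11.27
TTMPLW	1	5.32	5.71
TLTGKTITLEVEPSDTIENVK	2	5.42	5.24
TLSDYNIQKESTLHLVLR	2	5.23	4.67
TLSDYNIQKESTLHLVLR	3	2.35	2.33
TITLEVEPSDTIENVKAK	2	4.61	4.29
TITLEVEPSDTIENVKAK	3	2.17	2.20
TITLEVEPSDTIENVK	1	18.11	16.50
TITLEVEPSDTIENVK	2	4.15	3.73
IQDKEGIPPDQQR	1	13.45	13.04
IQDKEGIPPDQQR	2	2.44	3.02
IQDKEGIPPDQQR	3	1.26	1.54
LIFAGKQLEDGR	1	13.18	11.94
LIFAGKQLEDGR	2	2.53	2.65
LIFAGKQLEDGR	3	1.35	1.46
TLSDYNIQK	1	9.39	9.45
TLSDYNIQK	2	1.71	1.86
ESTLHLVLR	1	9.3	9.21
ESTLHLVLR	2	1.99	1.91
EGIPPDQQR	1	8.12	8.84
EGIPPDQQR	2	1.53	1.84
MQIFVK	1	6.11	5.95
MQIFVK	2	1.26	1.29
QLEDGR	1	5.69	5.33
QLEDGR	2	1.35	1.27
LIFAGK	1	4.96	4.85
LIFAGK	2	1.08	1.16
TLTGK	1	3.16	3.62
IQDK	1	3.02	3.11
ADTIVAVELDTYPNTDIGDPSYPHIGIDIK	3	3.61	3.65
DQKDLILQGDATTGTDGNLELTR	2	6.23	5.75
DLILQGDATTGTDGNLELTR	2	4.69	4.70
VGLSASTGLYK	2	1.99	2.05
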