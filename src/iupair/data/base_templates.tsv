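# residue	atom	element	x	y	z	charge	rmin_half	epsilon
A	N9	N	 -1.2910	  4.4980	  0.0000	 -0.0251	1.8240	0.1700
A	C8	C	  0.0240	  4.8970	  0.0000	  0.2006	1.9080	0.0860
A	N7	N	  0.8770	  3.9020	  0.0000	 -0.6073	1.8240	0.1700
A	C5	C	  0.0710	  2.7710	  0.0000	  0.0515	1.9080	0.0860
A	C6	C	  0.3690	  1.3980	  0.0000	  0.7009	1.9080	0.0860
A	N6	N	  1.6110	  0.9090	  0.0000	 -0.9019	1.8240	0.1700
A	N1	N	 -0.6680	  0.5320	  0.0000	 -0.7615	1.8240	0.1700
A	C2	C	 -1.9120	  1.0230	  0.0000	  0.5875	1.9080	0.0860
A	N3	N	 -2.3200	  2.2900	  0.0000	 -0.6997	1.8240	0.1700
A	C4	C	 -1.2670	  3.1240	  0.0000	  0.3053	1.9080	0.0860
A	H8	H	  0.3264	  5.9338	  0.0000	  0.1553	1.4090	0.0150
A	H2	H	 -2.6999	  0.2843	  0.0000	  0.0473	1.4090	0.0150
A	H61	H	  2.4013	  1.5379	  0.0000	  0.4115	0.6000	0.0157
A	H62	H	  1.7605	 -0.0899	  0.0000	  0.4115	0.6000	0.0157
G	N9	N	 -1.2890	  4.5510	  0.0000	  0.0492	1.8240	0.1700
G	C8	C	  0.0230	  4.9620	  0.0000	  0.1374	1.9080	0.0860
G	N7	N	  0.8700	  3.9690	  0.0000	 -0.5709	1.8240	0.1700
G	C5	C	  0.0710	  2.8330	  0.0000	  0.1744	1.9080	0.0860
G	C6	C	  0.4240	  1.4600	  0.0000	  0.4770	1.9080	0.0860
G	O6	O	  1.5540	  0.9550	  0.0000	 -0.5597	1.6612	0.2100
G	N1	N	 -0.7000	  0.6410	  0.0000	 -0.4787	1.8240	0.1700
G	C2	C	 -1.9990	  1.0870	  0.0000	  0.7657	1.9080	0.0860
G	N2	N	 -2.9490	  0.1390	  0.0000	 -0.9672	1.8240	0.1700
G	N3	N	 -2.3420	  2.3640	  0.0000	 -0.6323	1.8240	0.1700
G	C4	C	 -1.2650	  3.1770	  0.0000	  0.1222	1.9080	0.0860
G	H8	H	  0.3220	  5.9998	  0.0000	  0.1640	1.4090	0.0150
G	H1	H	 -0.5496	 -0.3577	  0.0000	  0.3424	0.6000	0.0157
G	H21	H	 -2.6886	 -0.8369	  0.0000	  0.4364	0.6000	0.0157
G	H22	H	 -3.9243	  0.4014	  0.0000	  0.4364	0.6000	0.0157
C	N1	N	 -1.2850	  4.5420	  0.0000	 -0.0484	1.8240	0.1700
C	C2	C	 -1.4720	  3.1580	  0.0000	  0.7538	1.9080	0.0860
C	O2	O	 -2.6280	  2.7090	  0.0000	 -0.6252	1.6612	0.2100
C	N3	N	 -0.3910	  2.3440	  0.0000	 -0.7584	1.8240	0.1700
C	C4	C	  0.8370	  2.8680	  0.0000	  0.8185	1.9080	0.0860
C	N4	N	  1.8750	  2.0270	  0.0000	 -0.9530	1.8240	0.1700
C	C5	C	  1.0560	  4.2750	  0.0000	 -0.5215	1.9080	0.0860
C	C6	C	 -0.0230	  5.0680	  0.0000	  0.0053	1.9080	0.0860
C	H5	H	  2.0544	  4.6869	  0.0000	  0.1928	1.4090	0.0150
C	H6	H	  0.1057	  6.1403	  0.0000	  0.1958	1.4090	0.0150
C	H41	H	  2.8180	  2.3887	  0.0000	  0.4234	0.6000	0.0157
C	H42	H	  1.7167	  1.0295	  0.0000	  0.4234	0.6000	0.0157
U	N1	N	 -1.2840	  4.5000	  0.0000	  0.0418	1.8240	0.1700
U	C2	C	 -1.4620	  3.1310	  0.0000	  0.4687	1.9080	0.0860
U	O2	O	 -2.5630	  2.6080	  0.0000	 -0.5477	1.6612	0.2100
U	N3	N	 -0.3020	  2.3970	  0.0000	 -0.3549	1.8240	0.1700
U	C4	C	  0.9890	  2.8840	  0.0000	  0.5952	1.9080	0.0860
U	O4	O	  1.9350	  2.0940	  0.0000	 -0.5761	1.6612	0.2100
U	C5	C	  1.0890	  4.3110	  0.0000	 -0.3635	1.9080	0.0860
U	C6	C	 -0.0240	  5.0530	  0.0000	 -0.1126	1.9080	0.0860
U	H3	H	 -0.4046	  1.3922	  0.0000	  0.3154	0.6000	0.0157
U	H5	H	  2.0584	  4.7870	  0.0000	  0.1811	1.4090	0.0150
U	H6	H	  0.0701	  6.1289	  0.0000	  0.2188	1.4090	0.0150
I	N9	N	 -1.2890	  4.5510	  0.0000	  0.0492	1.8240	0.1700
I	C8	C	  0.0230	  4.9620	  0.0000	  0.1374	1.9080	0.0860
I	N7	N	  0.8700	  3.9690	  0.0000	 -0.5709	1.8240	0.1700
I	C5	C	  0.0710	  2.8330	  0.0000	  0.1744	1.9080	0.0860
I	C6	C	  0.4240	  1.4600	  0.0000	  0.4770	1.9080	0.0860
I	O6	O	  1.5540	  0.9550	  0.0000	 -0.5597	1.6612	0.2100
I	N1	N	 -0.7000	  0.6410	  0.0000	 -0.4787	1.8240	0.1700
I	C2	C	 -1.9990	  1.0870	  0.0000	  0.5875	1.9080	0.0860
I	N3	N	 -2.3420	  2.3640	  0.0000	 -0.6323	1.8240	0.1700
I	C4	C	 -1.2650	  3.1770	  0.0000	  0.1222	1.9080	0.0860
I	H8	H	  0.3220	  5.9998	  0.0000	  0.1640	1.4090	0.0150
I	H1	H	 -0.5496	 -0.3577	  0.0000	  0.3424	0.6000	0.0157
I	H2	H	 -2.7883	  0.3499	  0.0000	  0.0473	1.4090	0.0150
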