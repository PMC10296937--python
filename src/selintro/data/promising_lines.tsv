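line_id	donor	treatment	rep	GYP	SF	FGN	SNP	TGW	PN	PH	HD
A-11	Bg90-2	normal	1	29.3	81.7	150.5	184.3	22.6	7.7	126.1	108.0
A-12	Bg90-2	normal	1	40.1	92.9	163.5	176.1	22.5	9.7	117.7	108.0
A-21	Bg90-2	normal	1	25.9	92.5	153.4	165.9	24.3	6.7	124.5	95.0
A-3	Bg90-2	normal	1	27.3	95.3	153.6	161.2	26.2	7.0	127.3	112.0
B-5	X21	normal	1	29.5	92.0	120.3	130.8	23.8	9.7	115.0	108.0
C-2	X22	normal	1	28.0	87.0	132.5	152.3	26.7	8.3	127.1	104.0
C-30	X22	normal	1	34.1	83.1	161.0	193.7	26.6	7.7	105.7	103.0
D-10	Q5	normal	1	32.9	92.5	149.6	161.7	25.4	8.7	130.8	108.0
D-9	Q5	normal	1	20.0	93.0	106.8	114.8	22.5	7.7	110.6	102.0
CY1	-	normal	1	22.6	87.5	124.0	134.2	24.2	7.2	124.3	105.3
A-11	Bg90-2	salt	1	12.8	63.0	473.0	187.8	23.5	4.0	96.0	107.0
A-12	Bg90-2	salt	1	10.9	68.6	386.0	140.8	26.5	4.0	89.0	108.0
A-21	Bg90-2	salt	1	14.6	73.5	476.0	162.0	27.5	4.0	93.0	107.0
A-3	Bg90-2	salt	1	8.4	83.9	224.0	133.5	27.0	2.0	85.0	108.0
B-5	X21	salt	1	9.4	66.0	285.0	72.0	23.3	6.0	76.0	118.0
C-2	X22	salt	1	11.5	78.4	373.0	95.2	22.0	5.0	84.0	115.0
C-30	X22	salt	1	13.9	73.2	583.0	132.7	23.3	6.0	118.0	106.0
D-10	Q5	salt	1	11.1	81.1	344.0	84.8	23.3	5.0	98.0	110.0
D-9	Q5	salt	1	11.7	63.1	352.0	93.0	26.3	6.0	91.0	112.0
CY1	-	salt	1	3.5	54.0	48.8	99.4	20.3	3.6	85.5	117.0
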