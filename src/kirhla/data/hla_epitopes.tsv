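allele	locus	amplicon_group	c_epitope	b_epitope	a_epitope
A*01:01	A	A	none	none	none
A*02:01	A	A	none	none	none
A*03:01	A	A	none	none	A3/A11
A*11:01	A	A	none	none	A3/A11
A*23:01	A	A	none	Bw4	none
A*24:02	A	A	none	Bw4	none
A*25:01	A	A	none	Bw4	none
A*26:01	A	A	none	none	none
A*29:02	A	A	none	none	none
A*30:01	A	A	none	none	none
A*31:01	A	A	none	none	none
A*32:01	A	A	none	Bw4	none
A*33:01	A	A	none	none	none
A*36:01	A	A	none	none	none
A*68:01	A	A	none	none	none
A*69:01	A	A	none	none	none
B*07:02	B	B	none	Bw6	none
B*08:01	B	B	none	Bw6	none
B*13:02	B	B	none	Bw4	none
B*14:02	B	B	none	Bw6	none
B*15:01	B	B	none	Bw6	none
B*18:01	B	B	none	Bw6	none
B*27:05	B	B	none	Bw4	none
B*35:01	B	B	none	Bw6	none
B*37:01	B	B	none	Bw4	none
B*38:01	B	B	none	Bw4	none
B*39:01	B	B	none	Bw6	none
B*40:01	B	B	none	Bw6	none
B*41:01	B	B	none	Bw6	none
B*44:02	B	B	none	Bw4	none
B*44:03	B	B	none	Bw4	none
B*46:01	B	B	C1	Bw6	none
B*47:01	B	B	none	Bw4	none
B*49:01	B	B	none	Bw4	none
B*50:01	B	B	none	Bw6	none
B*51:01	B	B	none	Bw4	none
B*52:01	B	B	none	Bw4	none
B*53:01	B	B	none	Bw4	none
B*55:01	B	B	none	Bw6	none
B*56:01	B	B	none	Bw6	none
B*57:01	B	B	none	Bw4	none
B*58:01	B	B	none	Bw4	none
B*73:01	B	C	C1	Bw6	none
C*01:02	C	C	C1	none	none
C*02:02	C	C	C2	none	none
C*03:03	C	C	C1	none	none
C*03:04	C	C	C1	none	none
C*04:01	C	C	C2	none	none
C*05:01	C	C	C2	none	none
C*06:02	C	C	C2	none	none
C*07:01	C	C	C1	none	none
C*07:02	C	C	C1	none	none
C*08:01	C	C	C1	none	none
C*08:02	C	C	C1	none	none
C*12:02	C	C	C1	none	none
C*12:03	C	C	C1	none	none
C*14:02	C	C	C1	none	none
C*15:02	C	C	C2	none	none
C*16:01	C	C	C1	none	none
C*17:01	C	C	C2	none	none
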