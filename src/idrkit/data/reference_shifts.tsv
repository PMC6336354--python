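# Backbone random-coil chemical shifts and full-structure secondary shifts (ppm)
# helix/sheet columns are the secondary shift of a fully formed alpha helix / beta sheet
residue_type	nucleus	rc_shift	helix_secondary	sheet_secondary
A	H	8.24	-0.3	0.45
A	N	123.8	-1.6	2.2
A	C	177.8	2.1	-1.2
A	CA	52.5	2.8	-1.4
A	CB	19.1	-0.5	2.5
C	H	8.32	-0.3	0.45
C	N	118.8	-1.6	2.2
C	C	174.6	2.1	-1.2
C	CA	58.2	2.8	-1.4
C	CB	28.0	-0.5	2.5
D	H	8.34	-0.3	0.45
D	N	120.4	-1.6	2.2
D	C	176.3	2.1	-1.2
D	CA	54.2	2.8	-1.4
D	CB	41.1	-0.5	2.5
E	H	8.42	-0.3	0.45
E	N	120.2	-1.6	2.2
E	C	176.6	2.1	-1.2
E	CA	56.6	2.8	-1.4
E	CB	29.9	-0.5	2.5
F	H	8.3	-0.3	0.45
F	N	120.3	-1.6	2.2
F	C	175.8	2.1	-1.2
F	CA	57.7	2.8	-1.4
F	CB	39.6	-0.5	2.5
G	H	8.33	-0.3	0.45
G	N	108.8	-1.6	2.2
G	C	174.9	2.1	-1.2
G	CA	45.1	2.8	-1.4
H	H	8.42	-0.3	0.45
H	N	118.2	-1.6	2.2
H	C	174.1	2.1	-1.2
H	CA	55.0	2.8	-1.4
H	CB	29.0	-0.5	2.5
I	H	8.0	-0.3	0.45
I	N	119.9	-1.6	2.2
I	C	176.4	2.1	-1.2
I	CA	61.1	2.8	-1.4
I	CB	38.8	-0.5	2.5
K	H	8.29	-0.3	0.45
K	N	120.4	-1.6	2.2
K	C	176.6	2.1	-1.2
K	CA	56.2	2.8	-1.4
K	CB	33.1	-0.5	2.5
L	H	8.16	-0.3	0.45
L	N	121.8	-1.6	2.2
L	C	177.6	2.1	-1.2
L	CA	55.1	2.8	-1.4
L	CB	42.4	-0.5	2.5
M	H	8.28	-0.3	0.45
M	N	119.6	-1.6	2.2
M	C	176.3	2.1	-1.2
M	CA	55.4	2.8	-1.4
M	CB	32.9	-0.5	2.5
N	H	8.4	-0.3	0.45
N	N	118.7	-1.6	2.2
N	C	175.2	2.1	-1.2
N	CA	53.1	2.8	-1.4
N	CB	38.9	-0.5	2.5
P	N	136.9	-1.6	2.2
P	C	177.3	2.1	-1.2
P	CA	63.3	2.8	-1.4
P	CB	31.7	-0.5	2.5
Q	H	8.32	-0.3	0.45
Q	N	119.8	-1.6	2.2
Q	C	176.0	2.1	-1.2
Q	CA	55.7	2.8	-1.4
Q	CB	29.4	-0.5	2.5
R	H	8.23	-0.3	0.45
R	N	120.5	-1.6	2.2
R	C	176.3	2.1	-1.2
R	CA	56.0	2.8	-1.4
R	CB	30.9	-0.5	2.5
S	H	8.31	-0.3	0.45
S	N	115.7	-1.6	2.2
S	C	174.6	2.1	-1.2
S	CA	58.3	2.8	-1.4
S	CB	63.8	-0.5	2.5
T	H	8.15	-0.3	0.45
T	N	113.6	-1.6	2.2
T	C	174.7	2.1	-1.2
T	CA	61.8	2.8	-1.4
T	CB	69.8	-0.5	2.5
V	H	8.03	-0.3	0.45
V	N	119.2	-1.6	2.2
V	C	176.3	2.1	-1.2
V	CA	62.2	2.8	-1.4
V	CB	32.9	-0.5	2.5
W	H	8.25	-0.3	0.45
W	N	121.3	-1.6	2.2
W	C	176.1	2.1	-1.2
W	CA	57.5	2.8	-1.4
W	CB	29.6	-0.5	2.5
Y	H	8.12	-0.3	0.45
Y	N	120.3	-1.6	2.2
Y	C	175.9	2.1	-1.2
Y	CA	57.9	2.8	-1.4
Y	CB	38.8	-0.5	2.5
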