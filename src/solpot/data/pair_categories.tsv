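aa1	aa2	category
F	F	pi-pi
F	Y	pi-pi
F	W	pi-pi
Y	Y	pi-pi
Y	W	pi-pi
W	W	pi-pi
H	F	His-pi
H	Y	His-pi
H	W	His-pi
H	H	His-pi
R	F	cation-pi
R	Y	cation-pi
R	W	cation-pi
K	F	cation-pi
K	Y	cation-pi
K	W	cation-pi
N	F	amino-pi
N	Y	amino-pi
N	W	amino-pi
Q	F	amino-pi
Q	Y	amino-pi
Q	W	amino-pi
D	F	anion-pi
D	Y	anion-pi
D	W	anion-pi
E	F	anion-pi
E	Y	anion-pi
E	W	anion-pi
K	D	Lys-salt-bridge
K	E	Lys-salt-bridge
G	G	aliphatic
G	A	aliphatic
G	V	aliphatic
G	I	aliphatic
G	L	aliphatic
A	A	aliphatic
A	V	aliphatic
A	I	aliphatic
A	L	aliphatic
V	V	aliphatic
V	I	aliphatic
V	L	aliphatic
I	I	aliphatic
I	L	aliphatic
L	L	aliphatic
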