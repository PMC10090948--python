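residue	formula
A	C3H5NO
C	C3H5NOS
D	C4H5NO3
E	C5H7NO3
F	C9H9NO
G	C2H3NO
H	C6H7N3O
I	C6H11NO
K	C6H12N2O
L	C6H11NO
M	C5H9NOS
N	C4H6N2O2
P	C5H7NO
Q	C5H8N2O2
R	C6H12N4O
S	C3H5NO2
T	C4H7NO2
V	C5H9NO
W	C11H10N2O
Y	C9H9NO2
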