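# SYNTHETIC example biophysical scale (helix-propensity-like, arbitrary units).
# These values are invented for demonstrating the scale-correlation interface
# only; they are NOT measured free energies and must not be cited as such.
# Replace with a real per-amino-acid scale (e.g. experimental helix/sheet
# free energies) to reproduce a biophysical analysis.
aa	value
A	0.00
C	0.68
D	0.69
E	0.40
F	0.54
G	1.00
H	0.61
I	0.41
K	0.26
L	0.21
M	0.24
N	0.65
P	3.16
Q	0.39
R	0.21
S	0.50
T	0.66
V	0.61
W	0.49
Y	0.53
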