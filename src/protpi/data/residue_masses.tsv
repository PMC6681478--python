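# Average residue masses (Da, amino acid minus one water) and elemental
# composition of the residue unit. The chain mass is the sum of residue
# masses plus one water (18.01524 Da, row "water").
# columns: residue	mass	C	H	N	O	S	Se
residue	mass	C	H	N	O	S	Se
A	71.0788	3	5	1	1	0	0
R	156.1875	6	12	4	1	0	0
N	114.1038	4	6	2	2	0	0
D	115.0886	4	5	1	3	0	0
C	103.1388	3	5	1	1	1	0
E	129.1155	5	7	1	3	0	0
Q	128.1307	5	8	2	2	0	0
G	57.0519	2	3	1	1	0	0
H	137.1411	6	7	3	1	0	0
I	113.1594	6	11	1	1	0	0
L	113.1594	6	11	1	1	0	0
K	128.1741	6	12	2	1	0	0
M	131.1926	5	9	1	1	1	0
F	147.1766	9	9	1	1	0	0
P	97.1167	5	7	1	1	0	0
S	87.0782	3	5	1	2	0	0
T	101.1051	4	7	1	2	0	0
W	186.2132	11	10	2	1	0	0
Y	163.1760	9	9	1	2	0	0
V	99.1326	5	9	1	1	0	0
U	150.0500	3	5	1	1	0	1
O	237.3030	12	19	3	2	0	0
water	18.01524	0	2	0	1	0	0
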