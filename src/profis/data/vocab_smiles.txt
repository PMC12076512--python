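# notation: smiles
# specials: <pad> <start> <end>
C
c
N
n
O
o
S
s
P
F
Cl
Br
I
[nH]
[NH]
(
)
=
#
-
1
2
3
4
5
6
7
8
9
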