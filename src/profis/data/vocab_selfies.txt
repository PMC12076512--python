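# notation: selfies
# specials: <pad> <start> <end>
[C]
[=C]
[#C]
[N]
[=N]
[#N]
[NH]
[O]
[=O]
[S]
[=S]
[P]
[=P]
[F]
[Cl]
[Br]
[I]
[B]
[CH3]
[NH2]
[OH]
[SH]
[Branch1]
[Branch2]
[Ring1]
[Ring2]
[=Ring1]
[=Ring2]
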