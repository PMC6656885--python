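# Canonical domain names for R-gene classification.
# Keys are Pfam / tool output names, values are the canonical label used in
# subgroup grammars (NBS, LRR, TIR, CC).  Edit or extend freely; unmapped
# names pass through verbatim.
NB-ARC: NBS
NBS: NBS
NB-LRR: NBS
LRR: LRR
LRR_1: LRR
LRR_2: LRR
LRR_3: LRR
LRR_4: LRR
LRR_5: LRR
LRR_6: LRR
LRR_8: LRR
LRRNT_2: LRR
TIR: TIR
TIR_2: TIR
CC: CC
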