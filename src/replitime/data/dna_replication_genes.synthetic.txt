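# Synthetic stand-in panel of 39 canonical human DNA-replication genes
# (origin licensing, CMG helicase, primase/polymerases, clamp and clamp
# loader, ssDNA binding, Okazaki maturation, fork helicase). Used by
# examples and tests wherever a curated replication-pathway gene list is
# needed; any user-supplied list is accepted in its place.
ORC1
ORC2
ORC3
ORC4
ORC5
ORC6
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
CDC6
CDT1
CDC45
GINS1
GINS2
GINS3
GINS4
POLA1
POLA2
PRIM1
PRIM2
POLD1
POLD2
POLE
POLE2
PCNA
RFC1
RFC2
RFC3
RFC4
RFC5
RPA1
RPA2
RPA3
FEN1
LIG1
PIF1
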