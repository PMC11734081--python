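# Default domain-role map: InterPro accessions tracked for each architectural role.
#
# N       NB-ARC nucleotide-binding domain (the central NLR ATPase module)
# L1-L4   the four leucine-rich-repeat InterPro entries tracked for mining
# C       N-terminal coiled-coil (Rx-type CC); defines the CN/CNL/CL classes
# T       Toll/interleukin-1 receptor homology (TIR); defines TN/TNL/TL
#
# C and T are editable: unlike N and L1-L4 there is no single canonical
# InterPro entry for either, so classification runs report the hash of the
# role map in force.
roles:
  N: [IPR002182]
  L1: [IPR001611]
  L2: [IPR011713]
  L3: [IPR013210]
  L4: [IPR025875]
  C: [IPR041118]
  T: [IPR000157]
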