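# Three-group partitions of the 20 standard amino acids for the seven
# physicochemical properties used by the "composition" descriptor set
# (CTD-style composition descriptors). Each property partitions the full
# alphabet into three disjoint groups; group order is meaningful (group1,
# group2, group3) and descriptor names are derived from it.
#
# This file is user-editable: substitute your own partitions as long as every
# property keeps the three groups disjoint and jointly covering all 20
# residues.
hydrophobicity:
  group1: [R, K, E, D, Q, N]          # polar
  group2: [G, A, S, T, P, H, Y]       # neutral
  group3: [C, L, V, I, M, F, W]       # hydrophobic
vdw_volume:
  group1: [G, A, S, T, P, D, C]       # 0-2.78
  group2: [N, V, E, Q, I, L]          # 2.95-4.0
  group3: [M, H, K, F, R, Y, W]       # 4.03-8.08
polarity:
  group1: [L, I, F, W, C, M, V, Y]    # 4.9-6.2
  group2: [P, A, T, G, S]             # 8.0-9.2
  group3: [H, Q, R, K, N, E, D]       # 10.4-13.0
polarizability:
  group1: [G, A, S, D, T]             # 0-1.08
  group2: [C, P, N, V, E, Q, I, L]    # 0.128-0.186
  group3: [K, M, H, F, R, Y, W]       # 0.219-0.409
charge:
  group1: [K, R]                      # positive
  group2: [A, N, C, Q, G, H, I, L, M, F, P, S, T, W, Y, V]  # neutral
  group3: [D, E]                      # negative
secondary_structure:
  group1: [E, A, L, M, Q, K, R, H]    # helix
  group2: [V, I, Y, C, W, F, T]       # strand
  group3: [G, N, P, S, D]             # coil
solvent_accessibility:
  group1: [A, L, F, C, G, I, V, W]    # buried
  group2: [R, K, Q, E, N, D]          # exposed
  group3: [M, S, P, T, H, Y]          # intermediate
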