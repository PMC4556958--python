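# Pharmacophore feature perception table, version 1.
#
# Each feature letter maps to a list of SMARTS patterns; every substructure
# match becomes one feature point at the centroid of the matched atoms.
# Conventions:
#   * ionisation follows the rule-based pH 7.4 convention: acids are treated
#     as deprotonated (N sites), aliphatic amines / amidines / guanidines as
#     protonated (P sites);
#   * overlap policy: aromatic rings yield R only (H patterns exclude aromatic
#     atoms); protonated amines yield P only (they are absent from A and D);
#     charged acid groups yield N only (A patterns exclude carboxyl oxygens);
#   * with h_cluster true, bond-connected hydrophobic atoms are merged into a
#     single site per cluster (one H per alkyl fragment, not per atom).
version: 1
h_cluster: true
patterns:
  A:
    - "[OX1]=[CX3;!$([CX3][OX2H1,OX1-])]"                 # carbonyl O (not carboxyl)
    - "[OX1]=[SX4;!$([SX4][OX2H1,OX1-])]"                 # sulfonyl/sulfoxide O
    - "[OX2;H0;+0;!$([OX2][CX3]=[OX1])]"                  # ether / ester sp3 O
    - "[OX2H1;+0;!$([OX2H1][CX3]=[OX1]);!$([OX2H1][SX4])]" # hydroxyl (also a donor)
    - "[nX2;+0]"                                          # pyridine-type aromatic N
    - "[NX2;+0;!$([NX2]=[OX1]);!$([NX2]=[CX3][NX3])]"     # imine N (not amidine/guanidine)
    - "[NX1]#[CX2]"                                       # nitrile N
  D:
    - "[OX2H1;+0;!$([OX2H1][CX3]=[OX1]);!$([OX2H1][SX4])]" # hydroxyl
    - "[NX3;H1,H2;$([NX3][CX3]=[OX1,SX1])]"               # amide / thioamide NH
    - "[NX3;H1,H2;$([NX3]a);!$([NX3][CX3]=[OX1])]"        # aniline-type NH
    - "[nX3;H1]"                                          # pyrrole-type NH
    - "[SX2H1]"                                           # thiol
  H:
    - "[C;!a;+0;!$(C~[!#6;!#1;!F;!Cl;!Br;!I])]"           # aliphatic C with only C/H/halogen neighbours
    - "[F,Cl,Br,I;$(*[#6])]"                              # halogen on carbon
  N:
    - "[CX3](=[OX1])[OX2H1,OX1-]"                         # carboxylic acid / carboxylate
    - "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]"                 # sulfonic acid / sulfonate
    - "[PX4](=[OX1])([OX2H1,OX1-])[OX2H1,OX1-]"           # phosphonate / phosphate
    - "c1nnn[nH,n-]1"                                     # tetrazole (acidic)
  P:
    - "[NX3;+0;!$([NX3][!#6;!#1]);!$([NX3]a);!$([NX3][CX3]=[OX1,SX1,NX2])]" # aliphatic amine
    - "[NX4+;!$([NX4+][OX1-])]"                           # quaternary / protonated N
    - "[NX3+;!$([NX3+][OX1-])]"                           # protonated sp2/sp3 N (explicit charge)
    - "[NX2;+0;$([NX2]=[CX3][NX3])]"                      # amidine / guanidine =N
  R:
    - "a1aaaa1"                                           # 5-membered aromatic ring
    - "a1aaaaa1"                                          # 6-membered aromatic ring
    - "a1aaaaaa1"                                         # 7-membered aromatic ring
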