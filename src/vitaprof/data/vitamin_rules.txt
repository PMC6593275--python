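# Pathway signature rules for B-vitamin and queuosine metabolism in human gut
# bacteria. One block per micronutrient; within a block, variant rules are
# ordered most-complete-first and matched first-hit-wins.
#
# Syntax
#   [vocabulary]          whitespace-separated functional role names
#   [B1] ... [Q]          ordered variant-rule blocks
#   CODE BP : terms       one pathway variant per line; BP is the binary
#                         phenotype (1 prototroph, 0 auxotroph)
#   terms                 comma-separated; (X) marks an optional role,
#                         X/Y/Z an any-of alternative group, a lone "-"
#                         an empty signature that matches any genome
#   | note                optional growth-requirement annotation
#
# "CbiMNQO" denotes the cobalt uptake transporter of the cobalamin pathway.

[vocabulary]
ThiF ThiS ThiH ThiO ThiG ThiC ThiD ThiE ThiL ThiN Thi4 ThiM
RibA RibB RibD RibH RibE RibF
NadA NadB NadB2 NadC NadD NadM NadE Tdo Kfa Kmo Kyn Had PncB NadV PncA NadR
PanD PanP PanB PanE PanG PanC CoaA CoaX CoaW CoaB CoaC CoaD CoaE
PdxS PdxT PdxJ PdxA PdxH PdxO PdxK PdxK2
BioF BioA BioB BioD BioC BioG BioH BioZ BioV BioW BirA
FolE1 FolE2 FolQ FolQ1 FolQ2 FolB FolB2 FolK FolP FolC PabC PabAB FolA FolA2 FolM
CbiK CbiX CbiX2 CbiL CbiH CbiF CbiG CbiD CbiJ CbiT CbiE CbiC CbiA CbiMNQO
CbiP CbiB CobU CobS CobC CblZ CobT CobD BtuR PduO ChlID CobN CobG CobF
QueA QueG QueH QueC QueF GCYHI1 GCYHI2 QueD QueE qTGT

[B1]
P1   1 : (ThiF), (ThiS), ThiH/ThiO, ThiG, ThiC, ThiD, ThiE, ThiL/ThiN
P1*  1 : (ThiF), (ThiS), ThiG, ThiC, ThiD, ThiE, ThiL/ThiN | (Ig source?)
P2   1 : Thi4, ThiC, ThiD, ThiE, ThiL/ThiN
Ah   0 : (ThiF), (ThiS), ThiH/ThiO, ThiG, ThiD, ThiE, ThiL/ThiN | B1; HMP
Az   0 : ThiC, ThiD, ThiE, ThiM, ThiL/ThiN | B1; HET
Ahz  0 : ThiD, ThiE, ThiM, ThiL/ThiN | B1; (HMP+HET)
A    0 : ThiL/ThiN | B1

[B2]
P    1 : (RibA), RibB, RibD, RibH, RibE, RibF
A    0 : RibF | B2

[B3]
P1   1 : NadA, NadB/NadB2, NadC, NadD/NadM, NadE
P1*  1 : NadA, NadC, NadD/NadM, NadE | (missing NadB?)
P2   1 : Tdo, (Kfa), Kmo, Kyn, (Had), NadC, NadD/NadM, NadE
Aq   0 : PncB, (PncA), NadC, NadD/NadM, NadE | B3; Qn
A    0 : PncB/NadV, (PncA), NadD/NadM, NadE | B3
Ar   0 : NadR | Nr

[B5]
P    1 : PanD/PanP, PanB, (PanE/PanG), PanC, CoaA/CoaX/CoaW, CoaB, CoaC, CoaD, CoaE
P*   1 : PanB, (PanE/PanG), PanC, CoaA/CoaX/CoaW, CoaB, CoaC, CoaD, CoaE | (beta-ala source?)
Apt  0 : PanD/PanP, PanC, CoaA/CoaX/CoaW, CoaB, CoaC, CoaD, CoaE | B5; Pnt
Apt* 0 : PanC, CoaA/CoaX/CoaW, CoaB, CoaC, CoaD, CoaE | B5; Pnt (beta-ala source?)
A    0 : CoaA/CoaX/CoaW, CoaB, CoaC, CoaD, CoaE | B5
Apn  0 : CoaA/CoaX/CoaW, CoaD, CoaE | Pantetheine
A*   0 : - | CoA uptake

[B6]
P1   1 : PdxS, (PdxT)
P2   1 : PdxJ, (PdxA), (PdxH/PdxO)
A    0 : PdxK/PdxK2 | B6
A*   0 : - | B6 (missing PdxK?)

[B7]
P1   1 : BioF, BioA, BioB, BioD, BioC, (BioG/BioH/BioZ/BioV), BirA
P2   1 : BioF, BioA, BioB, BioD, BioW, BirA
P*   1 : BioF, BioA, BioB, BioD, BirA | (pimeloyl source?)
A3   0 : BioA, BioB, BioD, BirA | B7; Dtb; DAPA; KAPA
A2   0 : BioD, BioB, BirA | B7; Dtb; DAPA
A1   0 : BioB, BirA | B7; Dtb
A    0 : BirA | B7

[B9]
P    1 : FolE1/FolE2, (FolQ/FolQ1/FolQ2), (FolB/FolB2), FolK, FolP, FolC, PabC, (PabAB), FolA/FolA2/FolM
P*   1 : FolE1/FolE2, (FolQ/FolQ1/FolQ2), (FolB/FolB2), FolK, FolP, FolC, FolA/FolA2/FolM | (pABA source?)
A    0 : FolA/FolA2/FolM | B9

[B12]
P1   1 : CbiK/CbiX/CbiX2, CbiL, CbiH, CbiF, CbiG, CbiD, CbiJ, CbiT, CbiE, CbiC, CbiA, CbiMNQO, CbiP, CbiB, CobU, CobS, CobC/CblZ, CobT, CobD, BtuR/PduO
P2   1 : ChlID, CobN, CbiL, CobG, CbiH, CbiF, CobF, CbiJ, CbiT, CbiE, CbiC, CbiA, CbiMNQO, CbiP, CbiB, CobU, CobS, CobC/CblZ, CobT, CobD, BtuR/PduO
Aba  0 : CbiA, CbiP, CbiB, CobU, CobS, CobC/CblZ, CobT, CobD, BtuR/PduO | B12; Cbi; Cbr; Ba
Acbr 0 : CbiP, CbiB, CobU, CobS, CobC/CblZ, CobT, CobD, BtuR/PduO | B12; Cbi; Cbr
Acbi 0 : CobU, CobS, CobC/CblZ, CobT, CobD, BtuR/PduO | B12; Cbi
A    0 : BtuR/PduO | B12

[Q]
P    1 : QueA, QueG/QueH, QueC, QueF, GCYHI1/GCYHI2, (QueD), QueE, qTGT
Ac   0 : QueA, QueG/QueH, QueC, QueF, qTGT | Q; preQ1; preQ0; CDG
Ao   0 : QueA, QueG/QueH, QueF, qTGT | Q; preQ1; preQ0
Ap   0 : QueA, QueG/QueH, qTGT | Q; preQ1
Aq   0 : qTGT | Q
A    0 : - | Not used
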