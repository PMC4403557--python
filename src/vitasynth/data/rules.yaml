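# Default producer criteria for the eight B-vitamin biosynthesis pathways.
#
# Grammar: each vitamin has one or more `lines`; a genome is a predicted
# producer iff at least one line is satisfied.  A line is a conjunction of
# terms joined by " + "; a term is a single role/subset id or an OR-group
# "(A or B)".  A subset id is present iff every member role is present.
#
# Compound mnemonics are expanded letter-wise into atomic roles.  Two naming
# collisions are resolved with qualified tokens (editable): the aerobic
# cobaltochelatase subunits are CobN/CobSch/CobTch (distinct proteins from
# the cobalamin synthase CobV and nucleotide-loop CobT), and cobalamin
# synthase CobS is tokenised CobV.  CbiKX is kept as one atomic role: it
# names a single chelatase family (CbiK/CbiX) treated as one functional role.
#
# `tolerance` allows a line to miss up to `max_missing` of the listed
# tolerable roles and still yield a producer call; `mandatory` roles can
# never be rescued by tolerance.  Only the pantothenate/CoA pathway uses
# this: a single missing enzyme among the early branched steps (KPHMT,
# KPRED, ASPDC) is tolerated, while the absence of pantothenate synthetase
# (PBAL) or any CoA step always yields a non-producer call.

roles:
  # biotin
  - BioW
  - BioC
  - BioF
  - BioA
  - BioD
  - BioB
  # cobalamin
  - CbiL
  - CobG
  - CbiG
  - CbiF
  - CobF
  - CbiD
  - CbiE
  - CbiC
  - CbiA
  - CobN
  - CobSch
  - CobTch
  - CobA
  - CobT
  - CbiP
  - CbiB
  - CobU
  - CobV
  - CbiKX
  - CysG
  # folate
  - FolE
  - FolB
  - FolK
  - FolP
  - pabAc
  - DHFS
  - DHFR
  - FPGS
  # niacin
  - ASPOX
  - QSYN
  - QAPRT
  - NaMNAT
  - NADS
  # pantothenate / CoA
  - KPHMT
  - KPRED
  - ASPDC
  - PBAL
  - PANK
  - PPCS
  - PPCDC
  - DPCK
  # pyridoxine
  - dxs
  - gapA
  - PdxB
  - PdxF
  - PdxA
  - PdxJ
  - PdxH
  - PdxT
  - PdxS
  # riboflavin
  - GTPCH2
  - PyrDR
  - DHBPS
  - DMRLS
  - RSA
  - RK
  - FMNAT
  # thiamin
  - ThiH
  - ThiO
  - ThiG
  - ThiS
  - ThiF
  - ThiC
  - ThiD
  - ThiE
  - Thi4
  # auxiliary roles: transporters, salvage and commonly-missing steps that
  # never enter producer calls but are tallied by role prevalence
  - BioY
  - BioG
  - BioH
  - PANF
  - RibU
  - PnuC
  - PdxK
  - FolQ
  - PyrP
  - pabAa
  - pabAb

subsets:
  BioFADB: [BioF, BioA, BioD, BioB]
  CbiLGF: [CbiL, CbiG, CbiF]
  CbiGF: [CbiG, CbiF]
  CbiECA: [CbiE, CbiC, CbiA]
  CobNST: [CobN, CobSch, CobTch]
  CobAT: [CobA, CobT]
  CbiPB: [CbiP, CbiB]
  CobUS: [CobU, CobV]
  FolEBKP: [FolE, FolB, FolK, FolP]
  PdxBFAJH: [PdxB, PdxF, PdxA, PdxJ, PdxH]
  PdxTS: [PdxT, PdxS]
  ThiGSF: [ThiG, ThiS, ThiF]
  ThiCDE: [ThiC, ThiD, ThiE]

vitamins:
  biotin:
    lines:
      - "BioW + BioFADB"
      - "BioC + BioFADB"
  cobalamin:
    # aerobic route first, then anaerobic
    lines:
      - "CbiL + CobG + CbiGF + (CobF or CbiD) + CbiECA + CobNST + CobAT + CbiPB + CobUS"
      - "(CbiKX or CysG) + CbiLGF + (CobF or CbiD) + CbiECA + CobAT + CbiPB + CobUS"
  folate:
    # dihydrofolate or tetrahydrofolate production suffices; FolQ is not
    # essential (commonly missing from annotations), pabAa/pabAb are not
    # essential (only pabAc of the PABA branch vetoes)
    lines:
      - "FolEBKP + pabAc + DHFS + DHFR + FPGS"
  niacin:
    lines:
      - "ASPOX + QSYN + QAPRT + NaMNAT + NADS"
  pantothenate:
    lines:
      - "KPHMT + KPRED + ASPDC + PBAL + PANK + PPCS + PPCDC + DPCK"
    tolerance:
      tolerable: [KPHMT, KPRED, ASPDC]
      max_missing: 1
    mandatory: [PBAL, PANK, PPCS, PPCDC, DPCK]
  pyridoxine:
    lines:
      - "dxs + gapA + PdxBFAJH"
      - "PdxTS"
  riboflavin:
    # PyrP is not essential (commonly missing from annotations)
    lines:
      - "GTPCH2 + PyrDR + DHBPS + DMRLS + RSA + RK + FMNAT"
  thiamin:
    # thiamin-monophosphate production suffices for producer status
    lines:
      - "(ThiH or ThiO) + ThiGSF + ThiCDE"
      - "Thi4 + ThiCDE"
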