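# Dual-state residue templates and transfer reactions for the protic ionic
# liquid 1-methylimidazolium acetate ([Im1H][OAc]) and its neutral pair
# 1-methylimidazole / acetic acid.
#
# Sign conventions: lj_epsilon and alpha are printed negative in CHARMM-style
# parameter tables; the loader stores magnitudes.  p_ref_percent values are
# divided by 100 at load time.
#
# The IM1H/IM1 atom block transcribes a published Drude general force field
# style parameterisation of the imidazolium/imidazole pair.  The HOAC/OAC
# atom block is a SYNTHETIC stand-in: per-atom values chosen to be
# CGenFF-plausible and exactly consistent with the 0/-1 e charge states, not
# a transcription of any published acetate parameter set.
residues:
  - protonated: IM1H
    deprotonated: IM1
    donor_atoms: [H7]
    acceptor_atoms: [N2]
    dummy_atoms: [H7]
    mapping: identity
    atoms_protonated:
      - {name: C1,    type: CD33F, lj_epsilon: -0.0486, lj_rmin_half: 2.040, charge: -0.182, alpha: -1.181, thole: 1.1}
      - {name: H1,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.135}
      - {name: H2,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.135}
      - {name: H3,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.135}
      - {name: N1,    type: ND2R5C, lj_epsilon: -0.0791, lj_rmin_half: 1.850, charge: 0.158, alpha: -0.803, thole: 1.0}
      - {name: C2,    type: CD2R5D, lj_epsilon: -0.0329, lj_rmin_half: 1.800, charge: -0.107, alpha: -1.083, thole: 1.1}
      - {name: H4,    type: HDR5D, lj_epsilon: -0.0350, lj_rmin_half: 0.700, charge: 0.195}
      - {name: C3,    type: CD2R5D, lj_epsilon: -0.0329, lj_rmin_half: 1.800, charge: -0.047, alpha: -1.083, thole: 1.1}
      - {name: H5,    type: HDR5D, lj_epsilon: -0.0350, lj_rmin_half: 0.700, charge: 0.192}
      - {name: C4,    type: CD2R5E, lj_epsilon: -0.0597, lj_rmin_half: 1.850, charge: -0.023, alpha: -1.253, thole: 1.2}
      - {name: H6,    type: HDR5E, lj_epsilon: -0.1000, lj_rmin_half: 0.550, charge: 0.203}
      - {name: N2,    type: ND2R5C, lj_epsilon: -0.0791, lj_rmin_half: 1.850, charge: -0.157, alpha: -0.803, thole: 1.0}
      - {name: H7,    type: HDP1A, lj_epsilon: -0.0100, lj_rmin_half: 0.400, charge: 0.363}
      - {name: LPN21, type: LPD,   lj_epsilon: -0.0000, lj_rmin_half: 0.010, charge: -0.000}
    atoms_deprotonated:
      - {name: C1,    type: CD33G, lj_epsilon: -0.0513, lj_rmin_half: 2.040, charge: -0.161, alpha: -1.081, thole: 1.0}
      - {name: H1,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.094}
      - {name: H2,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.094}
      - {name: H3,    type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.094}
      - {name: N1,    type: ND2R5A, lj_epsilon: -0.0578, lj_rmin_half: 1.861, charge: 0.140, alpha: -1.063, thole: 1.3}
      - {name: C2,    type: CD2R5A, lj_epsilon: -0.0523, lj_rmin_half: 2.070, charge: -0.369, alpha: -1.378, thole: 1.3}
      - {name: H4,    type: HDR5A, lj_epsilon: -0.0550, lj_rmin_half: 1.250, charge: 0.150}
      - {name: C3,    type: CD2R5A, lj_epsilon: -0.0523, lj_rmin_half: 2.070, charge: 0.188, alpha: -1.378, thole: 1.3}
      - {name: H5,    type: HDR5A, lj_epsilon: -0.0550, lj_rmin_half: 1.250, charge: 0.053}
      - {name: C4,    type: CD2R5B, lj_epsilon: -0.0680, lj_rmin_half: 1.980, charge: 0.118, alpha: -0.868, thole: 1.3}
      - {name: H6,    type: HDR5B, lj_epsilon: -0.0870, lj_rmin_half: 1.103, charge: 0.073}
      - {name: N2,    type: ND2R5B, lj_epsilon: -0.0511, lj_rmin_half: 1.956, charge: 0.000, alpha: -0.840, thole: 1.0}
      - {name: H7,    type: DUMH,  lj_epsilon: -0.0000, lj_rmin_half: 0.010, charge: 0.000}
      - {name: LPN21, type: LPD,   lj_epsilon: -0.0000, lj_rmin_half: 0.010, charge: -0.474}
  # SYNTHETIC stand-in parameter block (see header note).
  - protonated: HOAC
    deprotonated: OAC
    donor_atoms: [H4]
    acceptor_atoms: [O1, O2]
    dummy_atoms: [H4]
    mapping: identity
    atoms_protonated:
      - {name: C1, type: CD33H, lj_epsilon: -0.0780, lj_rmin_half: 2.040, charge: -0.270, alpha: -1.000, thole: 1.3}
      - {name: H1, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: H2, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: H3, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: C2, type: CD2OH, lj_epsilon: -0.0700, lj_rmin_half: 1.990, charge: 0.750, alpha: -1.200, thole: 1.3}
      - {name: O1, type: OD2C,  lj_epsilon: -0.1200, lj_rmin_half: 1.700, charge: -0.550, alpha: -0.850, thole: 1.3}
      - {name: O2, type: OD31,  lj_epsilon: -0.1900, lj_rmin_half: 1.760, charge: -0.610, alpha: -0.900, thole: 1.3}
      - {name: H4, type: HDP1A, lj_epsilon: -0.0100, lj_rmin_half: 0.400, charge: 0.410}
    atoms_deprotonated:
      - {name: C1, type: CD33I, lj_epsilon: -0.0780, lj_rmin_half: 2.040, charge: -0.370, alpha: -1.050, thole: 1.3}
      - {name: H1, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: H2, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: H3, type: HDA3A, lj_epsilon: -0.0240, lj_rmin_half: 1.340, charge: 0.090}
      - {name: C2, type: CD2OC, lj_epsilon: -0.0700, lj_rmin_half: 1.990, charge: 0.620, alpha: -1.300, thole: 1.3}
      - {name: O1, type: OD2D,  lj_epsilon: -0.1200, lj_rmin_half: 1.700, charge: -0.760, alpha: -0.950, thole: 1.3}
      - {name: O2, type: OD2D,  lj_epsilon: -0.1200, lj_rmin_half: 1.700, charge: -0.760, alpha: -0.950, thole: 1.3}
      - {name: H4, type: DUMH,  lj_epsilon: -0.0000, lj_rmin_half: 0.010, charge: 0.000}

reactions:
  - reactants: [IM1H, OAC]
    products: [IM1, HOAC]
    r_max: 1.55
    p_ref_percent: 99.4
    c: 300
  - reactants: [IM1, HOAC]
    products: [IM1H, OAC]
    r_max: 1.55
    p_ref_percent: 9.8
    c: 300
  - reactants: [IM1H, IM1]
    products: [IM1, IM1H]
    r_max: 1.55
    p_ref_percent: 20.1
    c: 300
  - reactants: [HOAC, OAC]
    products: [OAC, HOAC]
    r_max: 1.55
    p_ref_percent: 68.4
    c: 300
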