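# Versioned parameter presets for dimerslide.
#
# Units: concentrations in the unit given per block; rates in bp/s or s^-1;
# lengths in bp. V_max values for activity titrations are relative to the
# wild-type dimer (WT = 1).
version: 1

binding:
  # C-terminal domain of the motor subunit binding a 50 bp DNA duplex
  # (MST design: 16-point two-fold dilution series).
  CTD_DNA:
    K_half: 1.0
    h: 1.8
    F_min: 0.0
    F_max: 1.0
    unit: uM
  # Full complex binding fluorescent nucleosomes at 20 nM. Half-saturation
  # values are order-of-magnitude placeholders (not printed in the source
  # figures); cooperativity h ~ 2 reflects the two-complex binding mode.
  WT_nucleosome:
    K_half: 30.0
    h: 2.0
    F_min: 0.0
    F_max: 1.0
    unit: nM

stoichiometry:
  # Saturation titration: fluorescent nucleosomes held at 500 nM, protein
  # titrated through the breakpoint. ratio = complexes bound per nucleosome.
  WT_500nM:
    ratio: 2.0
    ligand_conc: 500.0
    slope_unsat: 2.0      # FU per nM protein below saturation
    slope_sat: 0.0        # flat above saturation
    unit: nM
  long_overhang_500nM:
    ratio: 3.0
    ligand_conc: 500.0
    slope_unsat: 2.0
    slope_sat: 0.0
    unit: nM

activity:
  # Initial-rate titrations (rate vs total protein, 100 nM nucleosome;
  # saturation near the 2:1 complex:nucleosome ratio).
  WT_sliding:   {V_max: 1.0, K_half: 100.0, h: 1.9, unit: nM}
  WT_atpase:    {V_max: 1.0, K_half: 100.0, h: 1.3, unit: nM}
  dCTD_sliding: {V_max: 0.2, K_half: 100.0, h: 1.9, unit: nM}
  dCTD_atpase:  {V_max: 2.0, K_half: 100.0, h: 1.3, unit: nM}
  EA_sliding:   {V_max: 0.0, K_half: 100.0, h: 1.9, unit: nM}
  EA_atpase:    {V_max: 0.0, K_half: 100.0, h: 1.3, unit: nM}

simulator:
  WT:
    k_step0: 1.0        # maximal coupled stepping rate, bp/s
    s_sense: 50.0       # flank-sensing midpoint, bp
    sense_width: 8.0    # logistic softness, bp
    k_atp: 2.2222222    # ATP turnover per active motor, s^-1
    p_arrest: 0.2       # arrest probability per eligible well crossing
    well_period: 10     # phasing-landscape well spacing, bp
    well_depth: 0.0
    k_leak: 0.0
  dCTD:
    k_step0: 0.2        # five-fold slower maximal sliding
    s_sense: 30.0       # shortened sensing range (< 40 bp)
    sense_width: 8.0
    k_atp: 4.4444444    # two-fold higher turnover
    p_arrest: 0.2
    well_period: 10
    well_depth: 0.0
    k_leak: 0.0         # undirected stepping handled by the blind zone

species:
  # Protomer species: motor_active = functional ATPase motor (E-to-A
  # Walker-motif mutants are dead); ctd_present = C-terminal DNA-binding
  # domain present.
  WT:     {motor_active: true,  ctd_present: true}
  EA:     {motor_active: false, ctd_present: true}
  WTdCTD: {motor_active: true,  ctd_present: false}
  EAdCTD: {motor_active: false, ctd_present: false}
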