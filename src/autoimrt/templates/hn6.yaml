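# Head-and-neck class solution (three prescription levels: 70/63/56 Gy in
# 35 fractions). Derived structures, beams, objectives and regional
# hot/cold rules follow the published HN.6 planning-script configuration.
site: hn6

required_rois:
  - CTV70
  - CTV63
  - CTV56
  - cord
  - brain_stem
  - rt_parotid
  - lt_parotid
  - larynx
  - mandible
  - rt_cochlea
  - lt_cochlea
  - oral_cavity
  - external

derivations:
  # CTV -> PTV setup margin (protocol-level parameter of this template)
  - {name: PTV70, op: expand, of: [CTV70], margin_mm: 5}
  - {name: PTV63, op: expand, of: [CTV63], margin_mm: 5}
  - {name: PTV56, op: expand, of: [CTV56], margin_mm: 5}
  # body contour pulled 5 mm inward from the skin
  - {name: external_5mm, op: contract_external, of: [external], margin_mm: 5}
  # planning risk volumes, 5 mm uniform margin
  - {name: cord_prv, op: expand, of: [cord], margin_mm: 5}
  - {name: brainstem_prv, op: expand, of: [brain_stem], margin_mm: 5}
  # PTVs kept 5 mm off the skin and excluding the PRVs
  - {name: modPTV70, op: mod_ptv, of: [PTV70, external_5mm, cord_prv, brainstem_prv]}
  - {name: modPTV63, op: mod_ptv, of: [PTV63, external_5mm, cord_prv, brainstem_prv]}
  - {name: modPTV56, op: mod_ptv, of: [PTV56, external_5mm, cord_prv, brainstem_prv]}
  # total target for beam geometry
  - {name: TPTV, op: union_all, of: [PTV70, PTV63, PTV56]}
  # optimization PTVs avoiding the higher-dose volumes
  - {name: optPTV63, op: opt_ptv, of: [modPTV63, modPTV70]}
  - {name: optPTV56, op: opt_ptv, of: [modPTV56, modPTV70, modPTV63]}
  # same, with a 1 cm gradient buffer around the higher-dose volumes
  - {name: optPTV63_m, op: opt_ptv_margin, of: [modPTV63, modPTV70], margin_mm: 10}
  - {name: optPTV56_m, op: opt_ptv_margin, of: [modPTV56, modPTV70, modPTV63], margin_mm: 10}
  # parotid volumes avoiding the targets
  - {name: rt_parotid_opt, op: avoid_ptv, of: [rt_parotid, TPTV]}
  - {name: lt_parotid_opt, op: avoid_ptv, of: [lt_parotid, TPTV]}
  # chained 1 cm conformality rings
  - {name: ring70, op: ring, of: [PTV70], margin_mm: 10}
  - {name: ring63, op: ring, of: [ring70, PTV63], margin_mm: 10, exclude: [PTV70]}
  - {name: ring56, op: ring, of: [ring63, PTV56], margin_mm: 10, exclude: [PTV70, PTV63, ring70]}
  - {name: ring50, op: ring, of: [ring56], margin_mm: 10,
     exclude: [PTV70, PTV63, PTV56, ring70, ring63]}

beams:
  # anterior obliques are width-capped at 14.5 cm to avoid beam splitting;
  # each keeps the field edge on its own side flush with target + margin.
  # Posterior obliques shield the posterior neck with a jaw fixed 20 mm
  # from the central axis.
  - {name: LSAO, gantry: 75,  collimator: 0,   couch: 15,  margin_mm: 8, coverage: both}
  - {name: LAO,  gantry: 15,  collimator: 15,  couch: 0,   margin_mm: 8,
     max_width_mm: 145, coverage: left_edge}
  - {name: LPO,  gantry: 148, collimator: 350, couch: 0,   margin_mm: 8,
     jaw_overrides: {x2: 20}}
  - {name: RPO,  gantry: 218, collimator: 10,  couch: 0,   margin_mm: 8,
     jaw_overrides: {x1: -20}}
  - {name: RAO,  gantry: 285, collimator: 0,   couch: 345, margin_mm: 8,
     max_width_mm: 145, coverage: right_edge}
  - {name: RSAO, gantry: 345, collimator: 350, couch: 0,   margin_mm: 8, coverage: both}

prescription:
  dose_cGy: 7000
  fractions: 35
  reference: {roi_center: CTV70}

objectives:
  - {roi: CTV56,          kind: min_dose,     dose_cGy: 5700, weight: 100}
  - {roi: CTV63,          kind: min_dose,     dose_cGy: 6350, weight: 100}
  - {roi: CTV70,          kind: min_dose,     dose_cGy: 7100, weight: 10}
  - {roi: modPTV70,       kind: max_dose,     dose_cGy: 7690, weight: 100}
  - {roi: modPTV70,       kind: min_dose,     dose_cGy: 7000, weight: 65}
  - {roi: optPTV63,       kind: max_dose,     dose_cGy: 6720, weight: 70}
  - {roi: optPTV63,       kind: min_dose,     dose_cGy: 6450, weight: 80}
  - {roi: optPTV63_m,     kind: uniform_dose, dose_cGy: 6550, weight: 5}
  - {roi: optPTV56,       kind: min_dose,     dose_cGy: 5700, weight: 100}
  - {roi: optPTV56_m,     kind: max_dose,     dose_cGy: 6125, weight: 100}
  - {roi: optPTV56_m,     kind: uniform_dose, dose_cGy: 5650, weight: 1}
  - {roi: PTV56,          kind: min_dose,     dose_cGy: 2800, weight: 1}
  - {roi: PTV63,          kind: min_dose,     dose_cGy: 3200, weight: 1}
  - {roi: PTV70,          kind: min_dose,     dose_cGy: 3000, weight: 30}
  - {roi: brain_stem,     kind: max_dose,     dose_cGy: 5000, weight: 100}
  - {roi: brainstem_prv,  kind: max_dose,     dose_cGy: 5500, weight: 33}
  - {roi: cord,           kind: max_dose,     dose_cGy: 4000, weight: 100}
  - {roi: cord_prv,       kind: max_dose,     dose_cGy: 4500, weight: 70}
  - {roi: mandible,       kind: max_dose,     dose_cGy: 7000, weight: 100}
  # mean-dose EUD surrogate for the parotid (a = 1)
  - {roi: lt_parotid_opt, kind: max_eud,      dose_cGy: 2350, weight: 20, eud_a: 1}
  - {roi: ring50,         kind: max_dose,     dose_cGy: 5000, weight: 10}
  - {roi: ring56,         kind: max_dose,     dose_cGy: 5600, weight: 100}
  - {roi: ring63,         kind: max_dose,     dose_cGy: 6300, weight: 50}
  - {roi: ring70,         kind: max_dose,     dose_cGy: 7000, weight: 100}

hotcold_rules:
  # hot levels sit at 110% of the next-lower prescription (6930 = 110% of
  # 63 Gy, 6160 = 110% of 56 Gy, 7560 = 108% of 70 Gy); stored absolute.
  - {name: hot_out_70, polarity: hot,  iso_level_cGy: 7000, subtract: [PTV70, ring70]}
  - {name: hot63,      polarity: hot,  iso_level_cGy: 6930, subtract: [PTV70, ring70]}
  - {name: hot56,      polarity: hot,  iso_level_cGy: 6160,
     subtract: [PTV70, PTV63, ring70, ring63]}
  - {name: hot70,      polarity: hot,  iso_level_cGy: 7560}
  - {name: cold70,     polarity: cold, iso_level_cGy: 7000, base: modPTV70}
  - {name: cold63,     polarity: cold, iso_level_cGy: 6300, base: optPTV63}
  - {name: cold56,     polarity: cold, iso_level_cGy: 5600, base: optPTV56}

regional_objectives:
  - {rule: hot_out_70, kind: max_dose, dose_cGy: 6800, weight: 100}
  - {rule: hot63,      kind: max_dose, dose_cGy: 6650, weight: 50}
  - {rule: hot56,      kind: max_dose, dose_cGy: 5880, weight: 5}
  - {rule: hot70,      kind: max_dose, dose_cGy: 7350, weight: 1}
  - {rule: cold70,     kind: min_dose, dose_cGy: 7000, weight: 100}
  - {rule: cold63,     kind: min_dose, dose_cGy: 6300, weight: 50}
  - {rule: cold56,     kind: min_dose, dose_cGy: 5600, weight: 10}

optimizer:
  initial_iterations: 200
  regional_iterations: 20
  convergence_tol: 1.0e-6

termination:
  max_rounds: 3
  min_relative_spot_change: 0.05

dose_model:
  mu_per_mm: 0.005
  sigma_mm: 3.0
  beamlet_size_mm: 5.0

dvh_levels_cGy: [7000, 6650, 6300, 5950, 5600, 5000, 4500, 4000]

# cosmetic display settings only; never used in computation
roi_colors:
  PTV70: red
  PTV63: green
  PTV56: blue
  cord: yellow
  brain_stem: orange
  rt_parotid: cyan
  lt_parotid: magenta
  external: gray
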