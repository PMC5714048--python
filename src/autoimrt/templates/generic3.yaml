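# Generic three-level template (60/50/40 Gy) for the synthetic generic
# phantom. Structurally mirrors the head-and-neck class solution with a
# simpler beam arrangement; NON-CLINICAL — numbers are illustrative only,
# for exercising the multi-level machinery on synthetic data.
site: generic3

required_rois: [CTV60, CTV50, CTV40, oar_left, oar_right, external]

derivations:
  - {name: PTV60, op: expand, of: [CTV60], margin_mm: 5}
  - {name: PTV50, op: expand, of: [CTV50], margin_mm: 5}
  - {name: PTV40, op: expand, of: [CTV40], margin_mm: 5}
  - {name: external_5mm, op: contract_external, of: [external], margin_mm: 5}
  - {name: modPTV60, op: mod_ptv, of: [PTV60, external_5mm]}
  - {name: modPTV50, op: mod_ptv, of: [PTV50, external_5mm]}
  - {name: modPTV40, op: mod_ptv, of: [PTV40, external_5mm]}
  - {name: TPTV, op: union_all, of: [PTV60, PTV50, PTV40]}
  - {name: optPTV50, op: opt_ptv, of: [modPTV50, modPTV60]}
  - {name: optPTV40, op: opt_ptv, of: [modPTV40, modPTV60, modPTV50]}
  - {name: ring60, op: ring, of: [PTV60], margin_mm: 10}
  - {name: ring50, op: ring, of: [ring60, PTV50], margin_mm: 10, exclude: [PTV60]}
  - {name: ring40, op: ring, of: [ring50, PTV40], margin_mm: 10, exclude: [PTV60, PTV50, ring60]}

beams:
  - {name: ANT, gantry: 0,   margin_mm: 8}
  - {name: LAO, gantry: 72,  margin_mm: 8, max_width_mm: 145, coverage: left_edge}
  - {name: LPO, gantry: 144, margin_mm: 8}
  - {name: RPO, gantry: 216, margin_mm: 8}
  - {name: RAO, gantry: 288, margin_mm: 8, max_width_mm: 145, coverage: right_edge}

prescription:
  dose_cGy: 6000
  fractions: 30
  reference: {roi_center: CTV60}

objectives:
  - {roi: CTV60,     kind: min_dose, dose_cGy: 6100, weight: 100}
  - {roi: modPTV60,  kind: min_dose, dose_cGy: 6000, weight: 65}
  - {roi: modPTV60,  kind: max_dose, dose_cGy: 6600, weight: 100}
  - {roi: optPTV50,  kind: min_dose, dose_cGy: 5000, weight: 80}
  - {roi: optPTV50,  kind: max_dose, dose_cGy: 5760, weight: 70}
  - {roi: optPTV40,  kind: min_dose, dose_cGy: 4000, weight: 80}
  - {roi: optPTV40,  kind: max_dose, dose_cGy: 4800, weight: 50}
  - {roi: oar_left,  kind: max_eud,  dose_cGy: 2000, weight: 20, eud_a: 1}
  - {roi: oar_right, kind: max_eud,  dose_cGy: 2000, weight: 20, eud_a: 1}
  - {roi: ring60,    kind: max_dose, dose_cGy: 6000, weight: 100}
  - {roi: ring50,    kind: max_dose, dose_cGy: 5000, weight: 50}
  - {roi: ring40,    kind: max_dose, dose_cGy: 4000, weight: 10}

hotcold_rules:
  - {name: hot_out_60, polarity: hot,  iso_level_cGy: 6000, subtract: [PTV60, ring60]}
  - {name: hot50,      polarity: hot,  iso_level_cGy: 5500, subtract: [PTV60, ring60]}
  - {name: hot60,      polarity: hot,  iso_level_cGy: 6480}
  - {name: cold60,     polarity: cold, iso_level_cGy: 6000, base: modPTV60}
  - {name: cold50,     polarity: cold, iso_level_cGy: 5000, base: optPTV50}
  - {name: cold40,     polarity: cold, iso_level_cGy: 4000, base: optPTV40}

regional_objectives:
  - {rule: hot_out_60, kind: max_dose, dose_cGy: 5800, weight: 100}
  - {rule: hot50,      kind: max_dose, dose_cGy: 5300, weight: 50}
  - {rule: hot60,      kind: max_dose, dose_cGy: 6300, weight: 1}
  - {rule: cold60,     kind: min_dose, dose_cGy: 6000, weight: 100}
  - {rule: cold50,     kind: min_dose, dose_cGy: 5000, weight: 50}
  - {rule: cold40,     kind: min_dose, dose_cGy: 4000, weight: 10}

optimizer:
  initial_iterations: 200
  regional_iterations: 20
  convergence_tol: 1.0e-6

termination:
  max_rounds: 3
  min_relative_spot_change: 0.05

dvh_levels_cGy: [6000, 5000, 4000, 3000]
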