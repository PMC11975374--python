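# Calibrated default parameterization of the hemocyte pathway model (v1).
#
# Units: amounts are arbitrary concentration units; capacities are per-minute
# first-order constants (per rate pool).  The calibration targets, with noise
# off: ~70% labeled intracellular methionine in resting cells and >=80% in
# activated cells after 20 min of Met-13C5; ~2-fold infected/uninfected SAM
# and SAH levels; and a SAM m+5 : ATP m+5 fraction ratio of ~0.13 under
# Ado-13C5 in activated cells.
version: 1
pool_amounts:
  Met: 1.0
  SAM: 1.0
  SAH: 0.3
  Hcy: 0.02
  CTH: 0.5
  MTA: 0.3
  Ado: 0.08
  AMP: 1.0
  ADP: 2.0
  ATP: 5.0
  IMP: 0.3
  R5P: 1.0
capacities:
  met_uptake: 0.065
  met_efflux: 0.053
  sam_synthetase: 0.0055
  methyltransferase: 0.055
  samdc_mta: 0.004
  mta_clearance: 0.006
  ahcy_forward: 0.034
  ahcy_reverse: 0.5
  remethylation: 0.0
  met_cth_bypass: 0.0
  cbs: 0.5
  cth_clearance: 0.02
  nucleotidase_5p: 0.0005
  ada: 0.023
  ent_export: 0.038
  adenosine_kinase: 0.0183
  adenylate_kinase_fwd: 0.08
  adenylate_kinase_rev: 0.12
  adp_regeneration: 0.0357
  de_novo_purine: 0.00134
  imp_to_amp: 0.022
  ado_uptake: 0.15
# share of the adenosine-kinase capacity carried by the infection-inducible
# isoform (Adk3-like); the remainder (Adk2-like) is constitutive.  Same idea
# for the cytosolic (Ak1-like) vs mitochondrial (Ak2-like) adenylate kinase.
adk3_share: 0.4
ak1_share: 0.5
infection_scales:
  methyltransferase: 1.2
  sam_synthetase: 1.85
  met_transport: 1.4
  de_novo_purine: 2.2
  adp_regeneration: 1.55
  adk3: 1.3
  ak1: 3.0
sah_inhibition_ki: 0.2
sam_feedback_ki: 1.0
ehna_split: 0.5
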