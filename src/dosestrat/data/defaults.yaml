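# Shipped defaults: ROI vocabulary, paired organs, per-symptom cluster
# feature windows and NTCP organ lists, and algorithm hyperparameters.
# Any block may be overridden by a user YAML passed to load_config().

roi_aliases:
  Parotid_L: left_parotid
  Parotid_R: right_parotid
  Lt Parotid: left_parotid
  Rt Parotid: right_parotid
  Submandibular_L: left_submandibular
  Submandibular_R: right_submandibular
  Lt Submandibular: left_submandibular
  Rt Submandibular: right_submandibular
  SMG_L: left_submandibular
  SMG_R: right_submandibular
  Hard_Palate: hard_palate
  Soft_Palate: soft_palate
  Upper_Lip: upper_lip
  Lower_Lip: lower_lip
  Oral_Cavity: oral_cavity
  Mylogeniohyoid: mylogeniohyoid
  Mylo_Geniohyoid: mylogeniohyoid
  Genioglossus: genioglossus
  Tongue: tongue
  Larynx: larynx
  Supraglottic_Larynx: supraglottic_larynx
  SupraglotticLarynx: supraglottic_larynx
  Esophagus: esophagus
  Inferior_Pharyngeal_Constrictor: ipc
  IPC: ipc
  Medial_Pharyngeal_Constrictor: mpc
  MPC: mpc
  Superior_Pharyngeal_Constrictor: spc
  SPC: spc
  Cricopharyngeal_Muscle: cricopharyngeal
  Mandible: mandible
  Spinal_Cord: spinal_cord
  SpinalCord: spinal_cord
  Brachial_Plexus: brachial_plexus

paired_organs:
  - [left_parotid, right_parotid]
  - [left_submandibular, right_submandibular]

# Per-symptom cluster organs and dose-at-volume windows (percent volume).
feature_specs:
  drymouth:
    organs: [ipsilateral_parotid, contralateral_parotid,
             ipsilateral_submandibular, contralateral_submandibular,
             hard_palate]
    vx_percent_lo: 25
    vx_percent_hi: 60
    vx_percent_step: 5
  swallow:
    organs: [ipc, mpc, supraglottic_larynx, esophagus, mylogeniohyoid]
    vx_percent_lo: 30
    vx_percent_hi: 65
    vx_percent_step: 5
  mucus:
    organs: [ipsilateral_parotid, contralateral_parotid,
             ipsilateral_submandibular, contralateral_submandibular]
    vx_percent_lo: 25
    vx_percent_hi: 65
    vx_percent_step: 5
  voice:
    organs: [tongue, ipc, larynx, supraglottic_larynx,
             contralateral_submandibular]
    vx_percent_lo: 45
    vx_percent_hi: 65
    vx_percent_step: 5

# Organs whose mean doses enter the recalibrated NTCP logistic models.
ntcp_organs:
  drymouth: [ipsilateral_parotid, contralateral_parotid,
             ipsilateral_submandibular, contralateral_submandibular,
             soft_palate, upper_lip, lower_lip, oral_cavity, mylogeniohyoid]
  swallow: [ipc, spc, supraglottic_larynx,
            ipsilateral_parotid, contralateral_parotid, cricopharyngeal]
  mucus: [soft_palate, hard_palate, oral_cavity, mandible, tongue,
          ipsilateral_parotid, contralateral_parotid]
  voice: [larynx, supraglottic_larynx, tongue, genioglossus, mylogeniohyoid]

clustering:
  n_components: 3
  covariance_type: full
  reg_covar: 1.0e-4
  n_init: 5
  weight_concentration_prior_type: dirichlet_process

rule_mining:
  beam_width: 25
  max_depth: 2
  max_thresholds: 64

outcomes:
  severe_threshold: 4
  min_completeness: 0.7
  imputer:
    hidden: [32, 16]
    corruption: 0.5
    learning_rate: 0.001
    max_epochs: 2000
    patience: 50
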