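# Base parameters for the flow-mediated reaction-zone coagulation model.
#
# PROVENANCE / SYNTHETIC NOTICE: the concizumab/TFPI extension rates
# (source: printed) are the published antibody and inhibitor kinetics.  All
# remaining entries (source: estimated) form a reduced, self-contained
# reconstruction of the predecessor reaction-zone model: values are drawn
# from standard coagulation kinetics and calibrated so that the platelet
# deposition, initiation and propagation timescales are physiological.
# They are NOT a transcription of the predecessor model's supplementary
# parameter set; see docs/methods.md.

geometry:
  rz_height_um: 1.0            # reaction-zone height above the 10x10 um injury
  # effective RZ concentration per unit TF surface density (calibrated;
  # folds in the fraction of surface TF accessible to the RZ volume)
  tf_nM_per_fmol_cm2: 0.025

flow:
  k_protein: 0.0025            # s^-1, first-order RZ <-> bulk exchange, proteins
  k_platelet: 0.5              # s^-1, platelets (margination-enhanced)

plasma:                        # upstream zymogen levels, nM (source: estimated)
  FVII: 10.0
  FVIIa: 0.0192
  FX: 170.0
  FIX: 90.0
  FII: 1400.0
  FV: 20.0
  FVIII: 1.0                   # 100 % level; hemophilia A runs scale this

platelets:
  quiescent_nM: 4.15e-4        # 2.5e8 platelets/mL as a molar concentration
  monolayer_nM: 0.111          # subendothelium-adhered monolayer in the RZ
  aggregate_cap_nM: 0.222      # cap on thrombin-activated aggregate platelets
  k_adhesion: 60.0             # s^-1 (times (1 - coverage)); transport-limited
  k_activation_thrombin: 0.5   # s^-1 once thrombin exceeds the threshold
  k_activation_contact: 0.3    # nM^-1 s^-1, activation by activated platelets
  thrombin_threshold_nM: 1.0

binding_sites:                 # per-platelet site numbers (source: estimated)
  N_Xa: 2700
  N_IX: 250
  N_V: 3000
  N_VIII: 450

membrane_binding:              # factor <-> platelet-site kinetics
  k_on: 1.0e7                  # M^-1 s^-1
  koff_Xa: 0.447               # s^-1
  koff_IXa: 0.025
  koff_V: 0.017
  koff_VIII: 0.017

rates:                         # M^-1 s^-1 / s^-1 unless noted
  # subendothelium (source: estimated except where printed)
  tf_viia_on: 5.0e6
  tf_viia_off: 2.44e-3
  tf_vii_act_xa: 3.75e7         # FXa-mediated activation of TF-bound FVII
  kX_on: 4.35e6                # printed
  kX_off: 1.0                  # printed
  kX_cat: 4.6                  # printed
  kXa_on: 1.92e6               # printed
  kXa_off: 1.0                 # printed
  se_ix_on: 1.0e7
  se_ix_off: 2.4
  se_ix_cat: 1.8
  kaXa_on: 1.6e7               # printed (TF:FVIIa:FXa + TFPIa)
  kaXa_off: 3.3e-4             # printed
  tfpixa_se_on: 1.6e7          # TFPIa:FXa rebinding TF:FVIIa
  tfpixa_se_off: 3.3e-4
  # plasma
  tfpi_xa_on: 1.0e6            # TFPIa + FXa, K_D = 20 pM
  tfpi_xa_off: 2.0e-5
  iia_fv: 5.0e1                # thrombin feedback activations (kcat/Km scale)
  iia_fvh: 2.5e2
  iia_fviii: 3.3e7
  xa_fv: 3.24e4                # FXa cleaving the FV B-domain -> FV-h
  kVh_on: 5.0e7                # printed (TFPIa / C:TFPIa binding FV-h)
  kVh_off: 4.5e-3              # printed
  # concizumab extension (printed)
  ka_on: 4.0e6
  ka_off: 1.0e-4
  # platelet membrane
  tenase_on: 1.0e8
  tenase_off: 0.2
  tenase_fx_on: 1.0e8
  tenase_fx_off: 8.0
  tenase_cat: 8.0
  ptase_on: 1.0e8
  ptase_off: 0.1
  ptase_ii_on: 1.0e8
  ptase_ii_off: 10.0
  ptase_va_cat: 30.0
  ptase_vh_cat: 30.0
  tfpi_xam_on: 1.2e7           # protein-S-scaled set (membrane-enhanced)
  tfpi_xam_off: 1.0e-4
  tfpifvh_xam_on: 1.2e7
  tfpifvh_xam_off: 1.0e-4
  # pseudo-first-order inhibition sinks (antithrombin etc.), s^-1
  decay_iia: 0.014
  decay_xa: 0.096
  decay_ixa: 1.0e-4
  decay_fviiia: 0.0056
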