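# Two-cohort demo: lean control vs obese-HFpEF soleus conditions.
# Profiles named here come from the built-in study registries
# (myoxi.study_section_profiles / study_mechanics_profiles /
# study_flow_profiles); any of them can be replaced by an inline
# mapping of profile fields.
seed: 13
cohorts:
  - name: control
    section_profile: control_soleus
    mechanics_profile: control_soleus
    flow_profile: control
    helix: {noise_sd: 4.0}
    n_replicates: 3
  - name: hfpef
    section_profile: hfpef_soleus
    mechanics_profile: hfpef_soleus
    flow_profile: hfpef
    helix: {noise_sd: 8.0}
    n_replicates: 3
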