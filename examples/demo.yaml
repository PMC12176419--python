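# Three simulated regions sharing one cohort design: an additive control,
# a rotation region (interaction present, category geometry preserved
# across tasks), and a reshape region (interaction present, geometry
# altered).  Sector statistics average the two interacting regions.
simulation:
  n_participants: 8
  n_runs_per_task: 8
  n_voxels: 80
regions:
  additive-ctrl: {geometry_mode: additive, interaction_gain: 0.0}
  ventral-like: {geometry_mode: rotation, interaction_gain: 0.8}
  dorsal-like: {geometry_mode: reshape, interaction_gain: 0.6}
sectors:
  interacting: [ventral-like, dorsal-like]
n_perm: 50
seed: 11
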