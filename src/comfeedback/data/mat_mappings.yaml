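# Variable-name mapping for the supplementary MATLAB archives.
#
# The internal structure of the archives is not documented; this table was
# authored against a best-guess layout (one struct array with one element per
# trial) and is expected to need per-file revision once the real archives are
# inspected. The importer raises ImportFormatError listing the variables it
# actually found whenever this mapping does not match.
#
# Layout contract per protocol:
#   trials_var: name of the top-level struct array (one element per trial)
#   fields: canonical field name -> MATLAB struct field name
version: 1
protocols:
  standing_translation:
    expected_protocol: standing_translation
    trials_var: trials
    fields: &canonical_fields
      subject_id: subject_id
      mass: mass
      com_height: com_height
      condition: condition
      walking_speed: walking_speed
      fs: fs
      analyzed_leg: analyzed_leg
      time: time
      com_pos: com_pos
      com_vel: com_vel
      ankle_angle: ankle_angle
      ankle_vel: ankle_vel
      ankle_moment: ankle_moment
      grf_vertical: grf_vertical
      cop_ap: cop_ap
      perturb_onset: perturb_onset
      perturb_direction: perturb_direction
      perturb_magnitude: perturb_magnitude
      events_left_hs: events_left_hs
      events_left_to: events_left_to
      events_right_hs: events_right_hs
      events_right_to: events_right_to
      emg_tibialis_anterior: emg_tibialis_anterior
      emg_soleus: emg_soleus
      emg_gastrocnemius: emg_gastrocnemius
      emg_norm_tibialis_anterior: emg_norm_tibialis_anterior
      emg_norm_soleus: emg_norm_soleus
      emg_norm_gastrocnemius: emg_norm_gastrocnemius
      foot_heel_ap: foot_heel_ap
      foot_toe_ap: foot_toe_ap
  pelvis_push:
    expected_protocol: pelvis_push
    trials_var: trials
    fields: *canonical_fields
  belt_discrete:
    expected_protocol: belt_discrete
    trials_var: trials
    fields: *canonical_fields
  belt_continuous:
    expected_protocol: belt_continuous
    trials_var: trials
    fields: *canonical_fields
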