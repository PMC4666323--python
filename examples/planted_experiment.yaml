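# Synthetic planted-signal experiment (qualitative analogue of the study's
# findings; all data are simulated). Reduced to 3 ROIs and 6 subjects so it
# runs in seconds — see graspmvpa.pipeline.preset_config("planted") for the
# full 7-ROI battery at 16 subjects.
design:
  n_runs: 4
  tr: 3.0
  volumes_per_run: 117
  conditions: [PGS, PGL, WHGS, WHGL, RS, RL]
  trials_per_condition: 45
  miniblock_size: 5
  isi_range: [3.0, 8.0]
  isi_mean_target: 4.9
  trial_duration: 2.0
  run_parity_rule: true
rois:
  - name: hAIP
    hemispheres: [L, R]
    n_voxels: 60
    effects:
      grasp_type: {L: 0.11, R: 0.0}   # grasp-type pattern in left hAIP only
      action_type: {L: 0.27, R: 0.22}
  - name: BA1/2/3ab
    hemispheres: [L, R]
    n_voxels: 60
    effects:
      grasp_type: {L: 0.11, R: 0.09}
      action_type: {L: 0.27, R: 0.22}
  - name: Control
    hemispheres: [none]
    n_voxels: 60
    effects: {}                        # out-of-brain control: pure noise
noise:
  white_sd: 1.0
  ar1_coef: 0.3
  drift_amplitude: 1.0
  drift_period: 128.0
hrf:
  peak_delay: 6.0
  undershoot_delay: 16.0
  peak_dispersion: 1.0
  undershoot_dispersion: 1.0
  ratio: 6.0
n_subjects: 6
subject_pattern_sd: 0.3
discard_volumes: 4
lag_volumes: 0
highpass_hz: 0.01
stats:
  q: 0.05
  include_control_in_family: true
seed: 7
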