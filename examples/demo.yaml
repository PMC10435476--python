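# Desk-scale demo run: simulate a vessel phantom, train the paired
# translator, enhance the AR volume and evaluate against the OR scan.
# Runs on one CPU in a few minutes.  `pamgan run --config demo.yaml`
seed: 0
out_dir: runs/demo
log_level: INFO
n_volumes: 2

phantom:
  kind: vessels
  extent: [640.0, 640.0, 640.0]
  n_seeds: 4
  branch_prob: 0.03
  vessel_diameter_range_um: [20.0, 60.0]
  tortuosity: 0.25

pitches: {dx: 10.0, dy: 10.0, dz: 10.0}

psf_ar:
  lateral_fwhm_focus_um: 80.0
  axial_fwhm_um: 27.0
  focal_depth_um: 320.0
  depth_of_focus_um: 640.0
  attenuation_length_um: 2000.0
  max_visible_depth_um: 1.0e+9
psf_or:
  lateral_fwhm_focus_um: 20.0
  axial_fwhm_um: 27.0
  focal_depth_um: 320.0
  depth_of_focus_um: 640.0
  attenuation_length_um: 2000.0
  max_visible_depth_um: 1.0e+9

noise_ar: {gaussian_sigma: 0.01}
noise_or: {gaussian_sigma: 0.01}

preprocess:
  patch_size: 64

generator: {n_res_blocks: 2, base_filters: 8, n_downsamples: 1}
discriminator: {base_filters: 8, n_layers: 2}

mode: cgan
train:
  epochs: 8
  lr: 0.001
  lr_decay_epochs: [6]
  batch_size: 4
  l1_weight: 100.0

evaluate:
  source: map
  signal_roi: [24, 40, 24, 40]
  noise_roi: [0, 8, 0, 8]
  profile_axis: lateral
  profile_index: 32
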