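# Full-scale acquisition profile: 4000 fps high-speed video of a head
# phantom, EVM band 10-1000 Hz at amplification factor 100, pixel pitch
# 0.49/0.46 mm per pixel, and the four DW-MRI condition time slots of an
# 87 s acquisition (b=0 then three diffusion encoding directions).
scene:
  width_px: 256
  height_px: 256
  fps: 4000
  duration_s: 4.4
  pixel_pitch_mm: [0.49, 0.46]
  background_level: 0.7
  texture_amp: 0.05
  noise_sigma: 0.005
  supersample: 8
  psf_sigma_px: 0.7
  seed: 0
  markers:
    - center_px: [128.0, 128.0]
      arm_length_mm: 10.0
      arm_width_mm: 2.0
      contrast: 0.5
band: {f_lo: 10.0, f_hi: 1000.0}
magnification: {alpha: 100.0}
gain: 101.0
segments:
  - {label: b0, t_start_s: 0.0, t_end_s: 12.0}
  - {label: direction_1, t_start_s: 12.0, t_end_s: 37.0}
  - {label: direction_2, t_start_s: 37.0, t_end_s: 62.0}
  - {label: direction_3, t_start_s: 62.0, t_end_s: 87.0}
resampling: {n_boot: 500, n_perm: 499, block_len_s: 0.1, seed: 0}
tracking: {search_radius_px: 5, min_corr: 0.6, method: paraboloid, template_psf_sigma_px: 0.7}
f_max_hz: 500.0
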