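# Desk-scale test profile: small synthetic idle/scan pair that the full
# pipeline can process in seconds. The scan condition vibrates the marker
# with a single 2.5 µm tone at 40 Hz (~0.005 px at 0.49 mm/px).
scene:
  width_px: 128
  height_px: 128
  fps: 1000
  duration_s: 2.0
  pixel_pitch_mm: [0.49, 0.46]
  background_level: 0.7
  texture_amp: 0.05
  noise_sigma: 0.005
  supersample: 8
  psf_sigma_px: 0.7
  seed: 0
  markers:
    - center_px: [64.0, 64.0]
      arm_length_mm: 10.0
      arm_width_mm: 2.0
      contrast: 0.5
scan_tones:
  - {amplitude_um: 2.5, frequency_hz: 40.0, axis: horizontal}
  - {amplitude_um: 2.0, frequency_hz: 55.0, axis: vertical}
band: {f_lo: 10.0, f_hi: 100.0}
magnification: {alpha: 100.0}
gain: 101.0
resampling: {n_boot: 500, n_perm: 499, block_len_s: 0.1, seed: 0}
tracking: {search_radius_px: 5, min_corr: 0.6, method: paraboloid, template_psf_sigma_px: 0.7}
f_max_hz: 500.0
output_dir: vibrotrack_out
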