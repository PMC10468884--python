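# Versioned default calibration for the porcine bowel-perfusion phantoms.
#
# Perfusion levels are on the relative 0-100 scale used throughout the
# package (percent of the maximally perfused reference).  The occlusion
# noise_sd values were set by scripts/calibrate_occlusion_noise.py so the
# default schedules yield the reported R^2 range; see docs/methods.md.
version: 1

gradient:
  plateau_level: 98.8        # mean over the perfused 8-10 cm segment
  watershed_level: 78.3      # target mean over the 4-6 cm window
  ischemic_level: 1.9        # mean over the 0-2 cm segment
  decline_onset_cm: 5.0      # slope break, 1 cm proximal to devascularization margin
  devasc_margin_cm: 4.0
  arc_offset: 16.6           # mesenteric minus antimesenteric, perfused zone
  mesenteric_share: 0.07229  # fraction of arc_offset above the centerline (1.2/16.6)
  ischemic_end_cm: 2.0
  plateau_start_cm: 8.0
  length_cm: 11.0
  band_width_cm: 5.0
  cold_pad_cm: 1.25          # dead (zero-flow) strip behind the staple line
  px_per_cm: 20.0

segments:                    # cm from the stapled edge
  ischemic: [0.0, 2.0]
  watershed: [4.0, 6.0]
  perfused: [8.0, 10.0]

occlusion:
  map_baseline_mmhg: 65.0    # invented; the source experiments print no MAP values
  end_scale: 0.05            # residual perfusion at complete occlusion
  arterial:
    map_end_mmhg: 20.0
    noise_sd: 9.2            # percent of full scale, calibrated (target R^2 ~ 0.96)
  venous:
    map_end_mmhg: 40.0       # venous congestion: small MAP drop, large perfusion drop
    noise_sd: 25.0           # calibrated (target R^2 ~ 0.86)

anastomosis:
  # 10 matched points, 0 to 4.5 cm; linear declines with the reported
  # means (54 / 38) and population SDs (18 / 15).
  am_profile: [82.2, 75.93, 69.67, 63.4, 57.13, 50.87, 44.6, 38.33, 32.07, 25.8]
  m_profile: [61.5, 56.28, 51.06, 45.83, 40.61, 35.39, 30.17, 24.94, 19.72, 14.5]
  span_cm: 4.5
  band_width_cm: 1.55
  px_per_cm: 20.0

optics:
  frame_rate: 120.0          # speckle frame rate, fps
  exposure_time: 0.005       # s; must stay below the 8.33 ms frame period
  speckle_grain_px: 1.0      # pixel:speckle ratio ~ 1:1
  bit_depth: 16
  mean_intensity: 1000.0
  mode: analytic
  substeps_per_frame: 64
  tau_static: 0.1            # s; correlation-time cap for zero flow
  tau_full_perfusion: 1.0e-4 # s; correlation time at perfusion 100

contrast:
  spatial_window: 7
  smooth_window: 5           # frames of temporal smoothing on flow-index maps
  k_floor: 0.05

rpu:
  area_px: 317               # region area; 21 is the alternate printed value
  n_frames: 5
  cardiac_window_s: 0.5

analysis:
  profile_spacing_cm: 0.5
  onset_window_cm: [2.0, 8.0]
  onset_slope_ratio: 2.0
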