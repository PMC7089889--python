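# Reference validation dataset of the physical implant-bone experiment the
# model emulates: published load-case force components, mean gauge strains
# (in vitro, with per-gauge SD in microstrain) and the corresponding model
# predictions, and full-field displacement spans per global axis.
load_cases:
  lc1: {FX: 101.19, FY: -836.19, FZ: -29.20}   # N
  lc2: {FX: -804.05, FY: -1957.53, FZ: -141.95}
orientation_deg: {adduction: 6.9, flexion: 2.0, anteversion: 12.7}
body_weight:
  mass_kg: 86.0
  g: 9.8
  load_1bw_N: 842.8
  load_range_bw: [0.33, 3.5]
  load_range_N: [280.9, 2949.8]
gauges:
  labels: [gauge1, gauge2, gauge3, gauge4]
  strain_invitro_ue: [-619.0, -388.5, 460.5, 36.5]
  strain_invitro_sd_ue: [5.2, 8.5, 2.9, 12.7]
  strain_insilico_ue: [-543.65, -508.12, 411.58, 39.997]
  error_pct: [12.17, 30.79, 10.62, 9.58]
displacement_spans:
  axes: [X, Y, Z]
  invitro_mm: [0.795, 0.53, 0.067]
  insilico_mm: [0.821, 0.561, 0.0749]
  error_pct: [3.27, 5.85, 11.79]
  ccc: 0.997
dic_uncertainty_m: 1.0e-6
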