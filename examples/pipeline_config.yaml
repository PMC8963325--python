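# Default simulated protocol comparison: four preparation protocols
# (FF, RTV, FFix, FFPS) x three replicate sections, default acquisition
# parameters (15 µm spot, 45 µm/s, 75/50 ms dwell), gelatin standards
# 0.9-450 µg/g plus blank.  Run with:
#   laims run --config examples/pipeline_config.yaml --out report/
seed: 1
n_replicates: 3
standard_solutions_ug_ml: [0.0, 1.0, 10.0, 50.0, 100.0, 250.0, 500.0]
gelatin_mass_g: 0.100
spike_volume_ml: 0.900
lines_per_standard: 10
p_offset_cps: 1100.0
reference_protocol: FF
protocols:
  FF:
    Zn: 1.0
    P: 1.0
    Fe: 1.0
  RTV:
    Zn: 0.97
    P: 0.999
    Fe: 0.962
  FFix:
    Zn: {stroma: 0.41, gland: 0.41, lumen: 0.41, hotspot: 1.0}
    P: 0.619
    Fe: 0.630
  FFPS:
    Zn: {stroma: 0.16, gland: 0.16, lumen: 0.16, hotspot: 0.50}
    P: 0.610
    Fe: 0.614
acquisition:
  spot_size_um: 15.0
  scan_speed_um_s: 45.0
  noise_multiplicative_cv: 0.05
  noise_additive_sd_cps: 30.0
segmentation:
  crop_shape_px: [100, 150]
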