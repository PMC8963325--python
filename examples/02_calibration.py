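"""Fit the matrix-matched gelatin calibration and quantify a zinc map.

Simulates the six spiked gelatin standards (0.9-450 µg/g) plus blank at
realistic noise, fits the line, and reports slope, R², LOD and LOQ.
"""

import laims as L
from laims.phantom import DEFAULT_STANDARD_SOLUTIONS_UG_ML

acq = L.AcquisitionConfig()
nominal = [L.standard_concentration(0.100, 0.900, c)
           for c in DEFAULT_STANDARD_SOLUTIONS_UG_ML]
print("nominal levels (µg/g):", [round(c, 1) for c in nominal])

standards = L.generate_standard_set(nominal, acq, lines_per_standard=10, seed=2)
levels = [L.make_level(ls, "64Zn", conc) for conc, ls in standards]
for lv in levels:
    print(f"  {lv.nominal_conc_ugg:7.1f} µg/g -> {lv.mean_intensity_cps:9.0f} cps "
          f"(between-line RSD {lv.rsd_pct:.1f}%)")

cal = L.fit_calibration(levels)
print(f"\nslope     {cal.slope_cps_per_ugg:.2f} cps per µg/g")
print(f"intercept {cal.intercept_cps:.1f} cps (gas background)")
print(f"R²        {cal.r_squared:.5f}  (linearity check: R² >= 0.996)")
print(f"LOD/LOQ   {cal.lod_ugg:.2f} / {cal.loq_ugg:.2f} µg/g "
      "(3σ and 10σ of the blank's line means over the slope; ratio 0.3)")

phantom = L.generate_phantom(seed=2)
maps = L.apply_protocol(phantom, L.default_protocols()["FF"])
ls = L.simulate_linescans(maps, acq, seed=2)
zn = L.quantify_map(L.lines_to_map(ls, "64Zn", 15.0), cal)
p = L.lines_to_map(ls, "31P", 15.0)
print(f"\nwhole-tissue zinc (P >= 1100 cps mask): "
      f"{L.tissue_average(zn, p):.0f} µg/g "
      "(glands 450, stroma 340 -> area-weighted mean near 390)")
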