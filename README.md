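# laims — quantitative LA–ICP–MS imaging of tissue sections

`laims` turns raw laser-ablation ICP-MS line scans into calibrated 2D
elemental maps, segments prostate tissue into biological compartments by a
transparent rule chain, and quantifies how sample-preparation protocols wash
elements out of the tissue.  It is written for analytical chemists and
imaging scientists who compare tissue preparation/storage protocols
(fresh-frozen vs vacuum-dried vs formalin-based) using elemental bioimaging,
and for anyone who needs a tested, deterministic reimplementation of this
style of MSI segmentation.

Because real measurements require an instrument, the package ships a
first-class synthetic data generator: a tissue *phantom* with known
compartment labels and concentrations is rendered through the same
acquisition model the pipeline inverts, so every stage can be verified
against ground truth.

## The science in brief

**Acquisition.** A laser rasters the section line by line (15 µm spot,
45 µm/s); the ablated aerosol is analysed per isotope (⁶⁴Zn/⁶⁶Zn at 75 ms
dwell, ³¹P/⁵⁷Fe at 50 ms).  Each channel's transient signal is bin-averaged
onto a common 15 µm pixel grid (one image row per line).

**Calibration.** Matrix-matched gelatin standards: spiking m = 100 mg
gelatin with v = 900 µL of a c = 1…500 µg/mL zinc solution gives nominal
concentrations c·v/(m + v) = 0.9…450 µg/g.  Ten lines per standard are
averaged and fitted by ordinary least squares,

    I = a·C + b,    LOD = 3σ_blank / a,    LOQ = 10σ_blank / a,

with σ_blank the standard deviation of the blank's line means (so LOD/LOQ =
0.3 identically).

**Segmentation.**  All rules operate on quantiles of the data, so they are
scale-free.  With Q(q) the linear-interpolation quantile:

- *tissue*: clip ³¹P to [Q(.25), Q(.50)], rescale to 8-bit, Gaussian blur
  (5×5), Otsu threshold; the largest filled connected component is tissue;
- *lumen*: a hole in the tissue with enclosed median ³¹P < Q(.45) whose
  surrounding ring (5×5 dilation) has median ³¹P > Q(.55);
- *gland/stroma*: clip on-tissue ³¹P to [Q(.05), Q(.95)], 8-bit, blur, Otsu,
  morphological opening (2×2), drop components < 0.05% of the image; pixels
  on/inside surviving components with ³¹P above the on-tissue median are
  gland epithelium, the rest stroma;
- *zinc hotspots* (prostatic calculi): luminal pixels with clipped ⁶⁴Zn
  above Q(.75) + 1.5·IQR of the 0.01–0.99-clipped data.

Quantitative analysis uses a 100 × 150 px crop (1500 × 2250 µm).

**Protocol comparison.**  Recovery(protocol, element) = 100 × mean(protocol)
/ mean(FF) over the ³¹P ≥ 1100 cps tissue mask; per-class box statistics and
the relative zinc budget (gland/stroma/hotspot fractions of total zinc)
quantify compartment-differential washout.

## Worked example

```python
import laims as L

phantom = L.generate_phantom(seed=1)                      # known ground truth
maps = L.apply_protocol(phantom, L.default_protocols()["FF"])
ls = L.simulate_linescans(maps, L.AcquisitionConfig(), seed=1)
p  = L.lines_to_map(ls, "31P", 15.0)
zn = L.lines_to_map(ls, "64Zn", 15.0)
seg = L.segment_section(p, zn)
print(seg.class_counts())
```

Running the shipped narrative scripts prints, for example
(`python examples/04_protocol_comparison.py`):

```
recovery rates (% of FF):
  FF    Fe 100.0%, P 100.0%, Zn 100.0%
  RTV   Fe  96.4%, P  99.8%, Zn  97.0%
  FFix  Fe  65.2%, P  61.8%, Zn  41.2%
  FFPS  Fe  63.4%, P  60.6%, Zn  16.0%
```

i.e. room-temperature vacuum drying (RTV) retains essentially everything,
formalin fixation (FFix) washes zinc down to ~41% of the fresh-frozen
reference, and paraffin sealing (FFPS) to ~16% — while the dense luminal
zinc deposits ("hotspots") survive fixation unscathed.  The other examples
walk through phantom construction (`01`), calibration with LOD/LOQ (`02`),
and segmentation scored against ground truth (`03`): at default acquisition
noise the rule chain reaches ~99% pixel accuracy and 100% hotspot
sensitivity.

A thin CLI mirrors the stages:

```
laims simulate --protocol FF --seed 1 --out scans/
laims convert  --input scans/ --channel 64Zn --out zn.tif
laims segment  --p-map p.tif --zn-map zn.tif --out seg/
laims run      --config examples/pipeline_config.yaml --out report/
```

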