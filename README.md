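# fundusqa

Quantitative analysis of wide-field fundus photographs: matched-filter
retinal vessel segmentation, artery/vein classification by optical density
ratio, vessel diameter / tortuosity / AVR metrics, digital channel
balancing for red-dominated trans-scleral illumination, and the ocular
light-safety exposure arithmetic that goes with contact-free trans-pars-planar
illumination. A synthetic fundus generator with exact ground truth makes the
whole pipeline testable end to end.

## Who this is for

Researchers prototyping quantitative retinal imaging pipelines — especially
for low-cost, nonmydriatic, wide-field cameras whose red-dominated images
defeat off-the-shelf tooling — and anyone who needs a seed-reproducible
vessel phantom with known per-segment diameter, tortuosity and artery/vein
labels to validate a measurement chain.

## The methods in brief

- **Channel balancing.** Trans-scleral illumination yields images whose red
  channel mean is ~4x the green and ~16x the blue. `balance_channels`
  rescales green to the red mean and drops the (signal-free) blue channel.
- **Vessel segmentation.** The green channel (highest vessel contrast) is
  convolved with a bank of zero-mean 2-D Gaussian matched filters — 12
  orientations x 10 scales = 120 kernels, Gaussian cross-profile
  `exp(-v²/2σ²)` along a support of length 6σ. The pixel-wise maximum over
  the bank is the enhanced vessel image; white top-hat filtering removes
  illumination drift and a global (Otsu) threshold, followed by a
  half-crest width refinement, gives the binary vessel map.
- **Artery/vein classification.** On vessel pixels the optical density
  ratio ODR = (R − G)/G is lower for arteries than veins. The map is
  skeletonised into centerline segments; a threshold over segment-mean ODRs
  labels each segment, with an optional width-based refinement
  (the artery is narrower than its accompanying vein).
- **Metrics.** Diameter: distance transform of the vessel map sampled along
  the centerline. Tortuosity: arc length / chord length (1 = straight).
  AVR = mean artery diameter / mean vein diameter (normal ≈ 0.54–0.82).
- **Light safety.** Pre-weighted power budgets: photochemical
  `t_max = limit / (power · transmission / area)` for trans-scleral
  exposure, the trans-pupillary variant without transmission, a thermal
  margin check against 700 mW/cm², and external↔eye field-of-view angle
  conversion (ratio 1.5).

## Worked example

```python
import fundusqa as fq

image, truth = fq.simulate_scene(seed=1)   # 512x512 phantom + ground truth
report = fq.analyze(image)                 # full pipeline

rep = report.av_report
print(rep.mean_artery_diameter_um, rep.mean_vein_diameter_um, rep.avr)
```

prints (seed 1):

```
153.3 207.1 0.740
```

i.e. the recovered mean artery diameter is 153.3 µm against a generated
truth of 162.2 µm, the vein mean 207.1 µm against 214.0 µm, and the
recovered AVR 0.740 against the true ratio 0.758 — inside the pipeline's
recovery targets (diameters ±10%, AVR ±0.08). Segmentation Dice against the
true mask is 0.877 and all 7 extracted segments get the correct
artery/vein label. The safety arithmetic reproduces its published worked
values: 2.4 h trans-scleral photochemical limit (0.5 mW, 30%, 13 mm²,
10 J/cm²), 30 min trans-pupillary bound at 9 mm², thermal margin 3.04x,
and 60° external = 90° eye-angle.

The `examples/` directory holds one short narrative script per capability
(`01_simulate_scene.py` … `05_light_safety.py`); each prints the numbers it
computes and what they mean. A thin CLI mirrors the library:

```bash
fundusqa simulate --seed 1 --out scene/
fundusqa analyze scene/fundus.png --out report/
fundusqa safety --power-mw 0.5 --thermal-intensity-mw-cm2 230
fundusqa selftest --seed 1
```

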