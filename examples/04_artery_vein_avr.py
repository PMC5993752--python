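"""Classify arteries vs veins and compute the AVR on a synthetic scene.

Each vessel segment's mean optical density ratio ODR = (R-G)/G is
thresholded (arteries lie below, veins above); diameters come from the
distance transform of the vessel map and tortuosity is arc/chord.  The
arteriolar-to-venular ratio (AVR) summarises artery narrowing: the normal
range is roughly 0.54-0.82.
"""

import fundusqa as fq

image, truth = fq.simulate_scene(seed=1)
report = fq.analyze(image)

print(f"analysis status: {report.status}; "
      f"{len(report.segments)} segments, ODR threshold {report.odr_threshold:.3f}")
print()
print(report.segments_frame().to_string(index=False))
print()
rep = report.av_report
true_avr = (truth.class_mean_diameter_um("artery")
            / truth.class_mean_diameter_um("vein"))
print(f"mean artery diameter {rep.mean_artery_diameter_um:6.1f} um  "
      f"(truth {truth.class_mean_diameter_um('artery'):6.1f})")
print(f"mean vein diameter   {rep.mean_vein_diameter_um:6.1f} um  "
      f"(truth {truth.class_mean_diameter_um('vein'):6.1f})")
print(f"AVR = {rep.avr:.3f} (reported {rep.avr_reported}); truth {true_avr:.3f}")
print(f"label accuracy vs truth: {fq.label_accuracy(report.segments, truth):.0%}")
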