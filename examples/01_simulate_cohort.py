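"""Simulate a labelled synthetic RF cohort and inspect its envelope statistics.

Each frame is a matrix of raw radio-frequency samples (axial sample x scan
line): resolvable point scatterers with Nakagami-distributed amplitudes,
convolved with a 3 MHz Gaussian pulse and attenuated with depth.  Positive
(MVI+) lesions attenuate more strongly (0.9 vs 0.5 dB/cm/MHz) and are more
pre-Rayleigh than negative ones.
"""

import numpy as np

import rfradiomics as rf
from rfradiomics.bmode import hilbert_envelope
from rfradiomics.synthetic import envelope_cell_peaks

cohort = rf.make_cohort(n_pos=3, n_neg=3, seed=0)
print(f"cohort: {len(cohort)} frames, "
      f"{sum(f.label for f in cohort)} positive, "
      f"frame shape {cohort[0].samples.shape} (samples x scan lines)")

frame = cohort[0]
r0, r1, c0, c1 = frame.lesion_roi.bounding_box
print(f"lesion ROI bounding box: rows {r0}..{r1}, cols {c0}..{c1} "
      f"({frame.lesion_roi.mask.sum()} pixels)")

# envelope peaks per resolution cell follow the generating Nakagami law
peaks = envelope_cell_peaks(frame, hilbert_envelope(frame))
print(f"per-cell envelope peaks: n={peaks.size}, "
      f"mean power {np.mean(peaks**2):.3f} "
      "(background omega is 1.0; attenuation pulls the average below it)")

# determinism: the same seed reproduces the cohort bit for bit
again = rf.make_cohort(n_pos=3, n_neg=3, seed=0)
print("bit-identical under the same seed:",
      all(np.array_equal(a.samples, b.samples) for a, b in zip(cohort, again)))
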