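"""Recover injected frame-to-frame motion from a phantom series.

The registration composes pairwise phase-correlation estimates to the
maximal-intensity reference frame; recovered translations are compared
against the phantom's known motion schedule.
"""

import numpy as np

from aifx import PhantomSpec, generate_phantom, register_series
from aifx.motion import mean_translations, reference_frame_index

rng = np.random.default_rng(7)
schedule = rng.uniform(-4.0, 4.0, size=(60, 2))
series, truth = generate_phantom(PhantomSpec(seed=2, motion_schedule=schedule))

corrected, fields = register_series(series)
ref = reference_frame_index(series)
relative_truth = truth.displacements - truth.displacements[ref]
recovered = mean_translations(fields, weight=truth.heart_mask().astype(float))

rms = np.sqrt(np.mean((recovered - relative_truth) ** 2))
print(f"injected translations: up to {np.abs(schedule).max():.2f} px")
print(f"reference frame: {ref} (near the LV bolus peak)")
print(f"RMS recovery error: {rms:.3f} px "
      "(sub-half-pixel error means curves are sampled from consistent anatomy)")
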