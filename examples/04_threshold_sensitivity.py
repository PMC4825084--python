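"""How the AIF extraction threshold changes the AIF peak and the MBF.

Lowering the bright-pixel percentile admits dimmer partial-volume rim
pixels into the LV ROI: the AIF peak drops and the deconvolved flow rises —
the directional bias expected from underestimating the AIF peak.
"""

import numpy as np

from aifx import generate_phantom, run_pipeline
from aifx.mbf import TissueCurves, forward_tissue, threshold_sensitivity
from aifx.phantom import random_spec

spec = random_spec(5, pv_rim_width=1.5, pv_rim_frac=0.5)
series, truth = generate_phantom(spec)
result = run_pipeline(series)

t = result.aif.times
aif_true = truth.spec.lv_curve(t)
tissue = TissueCurves(times=t, curves=np.stack([
    forward_tissue(t, aif_true, F, truth.spec.fermi_k, truth.spec.fermi_tau)
    for F in truth.flows]))

table = threshold_sensitivity(result.corrected, result.maps.lv_mask, tissue,
                              result.timing, qs=(75, 50, 25))
print(table.to_string(index=False))
print(f"\ntrue sector flow: {truth.flows[0]:.2f} ml/g/min")
print("lower percentile -> more (dimmer) pixels -> lower AIF peak -> higher MBF")
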