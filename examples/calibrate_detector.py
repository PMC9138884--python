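"""Calibrate an imperfect polarization line-scan detector.

A detector with per-pixel gain spread (±10%), polarizer-angle errors (±3°)
and finite extinction (200:1) measures a known rotating-polarizer sweep of
18 linear states; per-pixel 3×3 calibration matrices are fitted by
pseudoinverse and then applied to a fresh 10°-linear validation beam.
"""

import warnings

import numpy as np

from pclar import (DetectorConfig, StokesLinear, aop, apply_calibration,
                   dolp, fit_calibration)
from pclar.instrument import (generate_calibration_sweep, measure_beam,
                              rows_to_stokes)

detector = DetectorConfig.perturbed(seed=1)
measured, reference = generate_calibration_sweep(detector, seed=2)
cal = fit_calibration(rows_to_stokes(measured).transpose(2, 1, 0), reference)

rng = np.random.default_rng(3)
rows = measure_beam(StokesLinear.linear_beam(2000.0, 10.0), detector, rng=rng)
sm = rows_to_stokes(rows[None, :3, :])[0]
raw = StokesLinear(I=sm[0], Q=sm[1], U=sm[2])
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    corrected = apply_calibration(cal, raw)

for name, s in (("uncalibrated", raw), ("calibrated", corrected)):
    D, A = dolp(s), aop(s)
    print(f"{name:>13}: DoLP = {D.mean():.4f} ± {D.std():.4f}   "
          f"AoP = {A.mean():.3f} ± {A.std():.3f} deg")
print("true values:   DoLP = 1.0000            AoP = 10.000 deg")
print("Calibration centers both summaries on truth and sharply narrows the "
      "pixel-to-pixel spread.")
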