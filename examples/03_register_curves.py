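"""Align two risk curves in time by translation registration.

One resident's trajectory follows the same course as another's but a year
later (two grid slots on the half-yearly grid).  Registration recovers the
relative shift by iteratively aligning each curve to the mean curve.
"""

import numpy as np

from fdacbr import RiskSeries, fit_risk_curve, register_curves
from fdacbr.curves import RiskCurve

t = np.arange(1.0, 21.0)
base = fit_risk_curve(RiskSeries("early", t, 14 + np.sin(t / 3.0)), max_basis=8)
late = RiskCurve(base.knots + 2.0, base.order, base.coef, resident_id="late")

result = register_curves([base, late])
print(f"registration window: {result.window}")
print(f"translations delta: {np.round(result.deltas, 3)}")
print(f"recovered relative shift: {result.deltas[1] - result.deltas[0]:+.3f} "
      f"(true shift +2.0 slots = one year)")
print(f"REGSSE per sweep: {[round(x, 6) for x in result.regsse]}")
print(f"converged: {result.converged}")
print("\nREGSSE (the integrated squared deviation from the mean curve) can")
print("only decrease across sweeps; after alignment the two curves overlay")
print("and their distance reflects shape, not timing.")
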