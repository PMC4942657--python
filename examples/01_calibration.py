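"""Fit and invert a calibration curve.

Builds a six-level calibration for loganin on its published response line
(area = 14317*C - 32209), fits it by OLS, and inverts a sample area back to
a concentration.  The recovered slope/intercept equal the generating line
and the inversion lands inside the validated range.
"""

from qams import fit_calibration, invert_calibration

concentrations = [12.97, 25.95, 51.9, 103.8, 207.6, 415.2]  # µg/mL
points = [(c, 14317 * c - 32209) for c in concentrations]

curve = fit_calibration(points, "loganin")
print(f"fitted: area = {curve.slope:.0f} * C {curve.intercept:+.0f}   r = {curve.r:.4f}")
print(f"validated range: {curve.range[0]:.2f} - {curve.range[1]:.2f} µg/mL")

area = curve.predict(292.8)
result = invert_calibration(curve, area)
print(f"area {area:.0f} -> {result.concentration:.1f} µg/mL ({result.flag})")
# -> 292.8 µg/mL, in range: with the 2 g / 50 mL prep this is the 7.32 mg/g
#    loganin content of a typical crude Fructus Corni sample.
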