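"""Exhaustive two-band index optimization on planted-signal spectra.

The planted generator hides an exact DSI-LPC relation at a known band pair
(850, 950 nm by default) at signal-to-noise ~5; the scan must find it among
all 751 x 750 ordered pairs.
"""

import specphos as sp

s = sp.generate_planted(sp.SynthConfig(mode="planted", seed=1))
for kind in ("NDSI", "DSI", "RSI"):
    res = sp.scan_pairs(s.reflectance, s.lpc, kind, s.wavelengths)
    print(f"{kind}: best pair ({res.best.lambda_m:.0f}, {res.best.lambda_n:.0f}) nm"
          f"  r^2 = {res.best_r2:.3f}  (signed r = {res.best_r:+.3f})")
print("DSI recovers the planted pair exactly; NDSI and RSI find it too "
      "because all three indices are sensitive to the planted difference "
      "signal at this noise level.")
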