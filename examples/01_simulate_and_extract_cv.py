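"""Simulate one redox-probe voltammogram and extract its peak features.

The generator places an exponentially-modified-Gaussian oxidation peak on
the forward sweep and a reduction peak on the reverse sweep; the extractor
recovers peak potentials, heights, onsets, widths and areas from the trace
alone.
"""

from aptascreen import default_cv_shape, extract_cv_features, simulate_cv

shape = default_cv_shape()  # anodic peak 0.30 V, cathodic 0.20 V, 10 uA
cv = simulate_cv(shape, window=(-0.5, 0.8), scan_rate=0.03, seed=42)
features = extract_cv_features(cv)

print("anodic  peak: E = %.3f V, I = %.2e A, area = %.2e A*V"
      % (features.anodic.E_peak, features.anodic.I_peak, features.anodic.S))
print("cathodic peak: E = %.3f V, I = %.2e A, area = %.2e A*V"
      % (features.cathodic.E_peak, features.cathodic.I_peak,
         features.cathodic.S))
print("dE = %.3f V, E_half = %.3f V, R(I) = %.3f, R(S) = %.3f"
      % (features.delta_E, features.E_half, features.R_I, features.R_S))
print()
print("dE is the anodic/cathodic peak separation (60 mV would be a fully")
print("reversible one-electron couple); the ratios near 1 say the probe")
print("reaction is symmetric on this electrode.")
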