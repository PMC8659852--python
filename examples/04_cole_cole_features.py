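"""Read capacitance features off the Cole-Cole transform of a spectrum.

The complex capacitance C*(w) = 1/(jwZ) separates capacitive relaxations:
its real part plateaus at the double-layer capacitance, and the loss
branch C'' dips between two separated relaxations.
"""

import numpy as np

from aptascreen import (CircuitSpec, circuit_impedance, cole_cole_transform,
                        default_frequencies, extract_eis_features)

# a blocking double-interface cell with two in-band relaxations
circuit = CircuitSpec("M2_nonfaradaic", {
    "Rs": 400.0, "CPE1_T": 4.0e-5, "CPE1_P": 0.90, "Rp1": 2e5,
    "CPE2_T": 5.0e-6, "CPE2_P": 0.85, "Rp2": 5e4,
    "W_R": 1500.0, "W_tau": 0.05, "W_P": 0.45})
spectrum = circuit_impedance(circuit, default_frequencies(60))
features = extract_eis_features(cole_cole_transform(spectrum))

print(f"C_dl      = {features.C_dl:.3e} F   (high-frequency C' plateau)")
print(f"omega_min = {features.omega_min:.1f} rad/s "
      f"({features.omega_min / (2 * np.pi):.1f} Hz)")
print(f"C_min     = {features.C_min:.3e} F   (active capacitance there)")
print(f"omega_max = {features.omega_max:.1f} rad/s")
print()
print("omega_min sits in the dip of the loss branch between the layer")
print("relaxation and the series-resistance relaxation; a featureless")
print("(single-relaxation) cell reports NaN for the extrema instead.")
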