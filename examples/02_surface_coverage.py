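"""Quantify how much of the electrode a blocking layer covers.

A self-assembled monolayer blocks the redox probe's access to the
electrode, attenuating its oxidation peak.  Coverage is the percentage
drop of the anodic peak area between the bare and the modified electrode.
"""

from aptascreen import (default_cv_shape, simulate_coverage_pair,
                        surface_coverage)

true_coverage = 68.0  # a dense aptamer+blocker layer
shape = default_cv_shape(noise_sd=2e-7)
bare, modified = simulate_coverage_pair(true_coverage, shape, seed=3)

estimate = surface_coverage(bare, modified)
print(f"generated coverage: {true_coverage:.1f} %")
print(f"estimated coverage: {estimate:.1f} %")
print()
print("The estimate comes from the anodic peak-area ratio; all")
print("Randles-Sevcik prefactors cancel, so no physical constants enter.")
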