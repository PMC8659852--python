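# Methods

`aptascreen` analyses the electrochemical response of an aptamer-based
biosensor measured twice per specimen — before and after incubation with a
blood-plasma sample — and asks which parts of that response separate
lung-cancer (LC) from healthy (H) plasma.  Because the package is developed
and validated against synthetic data, this note documents both the analysis
methods and exactly what the synthetic generator does and does not emulate.

## Measurement model

Two modalities are analysed.

**Cyclic voltammetry (CV).**  The potential is swept from −0.5 V to 0.8 V
(vs Ag/AgCl) and back at 0.03 V/s in a hexacyanoferrate(II/III) redox-probe
solution.  The forward sweep carries the probe's oxidation (anodic) peak,
the reverse sweep the reduction (cathodic) peak.  The biolayer on the
electrode attenuates and reshapes these peaks, so their geometry is the
signal carrier.

**Electrochemical impedance spectroscopy (EIS).**  Complex impedance is
recorded from 1 kHz down to 1 Hz (10 mV amplitude, near open-circuit
potential, no redox probe).  The spectrum is interpreted two ways: through
the Cole–Cole complex capacitance C*(ω) = 1/(jωZ(ω)), and through
equivalent-circuit fitting.

## CV feature extraction

Each sweep branch is reduced to a peak descriptor:

| symbol | meaning | definition used here |
|---|---|---|
| Ea, Ec | peak potentials | extremum of baseline-corrected current |
| Ia, Ic | peak currents | corrected magnitude at the extremum |
| Einit, Iinit | onset | first potential (sweeping toward the peak) where the corrected magnitude exceeds 5% of the peak height and stays above it |
| Ew | width | full width at half the corrected height |
| Esh | shape | approach-side half-width / trailing-side half-width |
| S | area | trapezoidal integral of the corrected magnitude over the above-threshold window |

Derived scalars: ΔE = |Ea − Ec|, R(I) = Ia/Ic, R(S) = Sa/Sc,
E½ = (Ea + Ec)/2.

Choices the data do not dictate, made once and exposed as parameters:

* **Baseline** — a least-squares line through the leading (approach-side)
  20% of each segment, the conventional tangent method.  Configurable via
  `baseline_fraction`.
* **Onset threshold** — 5% of peak height with a sustained-crossing
  requirement, robust to noise (`onset_fraction`).
* **Width/shape** — FWHM and the half-width ratio are scale-invariant and
  need no model fit.  A peak with a heavy diffusional tail past the maximum
  has Esh < 1; a symmetric peak has Esh = 1.
* **Magnitudes** — peak currents and areas are reported as positive
  magnitudes so the ratios R(I), R(S) are positive.
* **Area window** — the reported S is the area of the above-threshold
  region, i.e. ≈ 97–98% of the full analytic peak area at the default 5%
  threshold.  All area *ratios* (coverage, R(S)) are unaffected because the
  truncation is proportional for a common peak shape.

**Surface coverage** of a blocking layer is
(1 − S_after/S_before) × 100 on the anodic (oxidation) peak, using areas by
default (heights optional).  All Randles–Ševčík prefactors cancel in the
ratio, so no physical constants enter.

## Impedance modelling

Element laws: CPE impedance Z = 1/(T(jω)^α) (α = 1 is an ideal capacitor of
capacitance T); semi-infinite Warburg Z = σω^(−1/2)(1 − j); generalized
finite-length Warburg Z = R·tanh((jωτ)^P)/(jωτ)^P (transmissive boundary;
`coth` for the reflective variant).  The free exponent P models the
non-ideal diffusion seen on modified electrodes.  Topologies:

* `M0_randles_w` — Rs + [CPE ∥ (Rct + W)]: modified Randles cell for
  redox-probe (Faradaic) measurements.
* `M1_randles_w_extra` — M0 ⊕ [CPE′ ∥ R′]: a layer whose electron-transfer
  pathway has split into two processes.
* `M2_nonfaradaic` — Rs + [CPE1 ∥ Rp1] + [CPE2 ∥ (Rp2 + W)]: non-Faradaic
  double interface; the first block is the gold/solution double layer, the
  second the aptamer-layer/solution boundary.

With the semi-infinite Warburg variant, `W_tau`/`W_P` drop out of the free
parameter inventory.

**Fitting** minimizes Σ w_i |Z_model(ω_i) − Z_i|² with modulus weighting
w_i = 1/|Z_i|² by default (spectra span orders of magnitude in |Z|; unit
weighting is available).  Magnitude parameters are optimized in log space,
exponents through a logit transform, so positivity and α ∈ (0, 1) are
structural.  The optimizer is Levenberg–Marquardt with multi-start:

1. a data-driven heuristic (Rs from the high-frequency real part, arc
   resistances from the in-band span, CPE magnitudes from the
   high-frequency imaginary part);
2. a decade grid of CPE-T shifts around that heuristic — the heuristic
   cannot tell which CPE carries which magnitude, and this label/magnitude
   mismatch is empirically the dominant local-minimum trap;
3. eight further deterministic log-space perturbations.

The search exits early once a numerically exact fit (χ² < 10⁻¹⁴·n) is
found, so the full grid only runs on hard spectra.  Standard errors come
from the Jacobian at the optimum via the delta method; model comparison
uses the least-squares AIC, with exact ties broken toward fewer parameters.
AIC comparison is only meaningful on noisy spectra: on noise-free synthetic
data every nesting reaches the numerical floor and the comparison
degenerates.

**CPE-to-capacitance conversion** offers the two standard formulas
(Hsu–Mansfeld: C = T·ω_peak^(α−1); Brug: C = T^(1/α)(1/Rs + 1/Rct)^((α−1)/α))
as alternatives, not asserted equalities — they can differ by tens of
percent and agree only at α = 1.

**Cole–Cole features.**  C_dl is the median C′ over the top half-decade of
frequency.  ω_min and ω_max are the most prominent interior local
minimum/maximum of the loss branch C″ against log-frequency, and C_min is
the active capacitance C′ at ω_min.  C′(ω) itself is monotone for every
physically sensible circuit examined here, so the relaxation structure —
loss peaks and the dip between two separated relaxations — is read off C″.
For cells whose series-resistance relaxation falls inside the measured band,
the C_dl plateau under-reads the true interfacial capacitance; it remains
monotone in the generating CPE-T, which is what classification needs.
Absent extrema are reported as missing values, never as errors, and
propagate as NaN through the feature table.

**Decision rule.**  On before/after M2 fits, a sample is called positive
when the electrode-interface CPE1-T dropped by ≥ 1 order of magnitude
*and* the biolayer CPE2-T rose; both thresholds are configurable.  The
physical picture: target binding pulls double-layer capacitance away from
the electrode/solution interface and adds it at the layer/solution
boundary.

## Change features and the feature table

Every base feature P measured before (P₀) and after (P_pl) incubation
yields two change features:

    Dlt[P]  = P₀ − P_pl
    Incr[P] = Dlt[P] / P₀ × 100   (percent; undefined at P₀ = 0 → NaN)

Two base registries exist: `paper12` (8 CV + 4 EIS quantities; 12 base + 24
change columns) and `full` (all 18 CV + 4 EIS quantities; 22 base + 44
change columns).  The full set is the default for screening; the columns
hold the before-state value plus both change features, grouped base-first.
Missing sub-features propagate as NaN and are imputed *within training
folds* downstream — never globally, which would leak held-out information
into the folds.

## Combination screening

Every feature subset of size 1, 2 or 3 is scored against a fixed bank of
nine interpretable classifiers — k-NN (k = 1, 3, 5), linear soft-margin
SVMs (C = 0.1, 1, 10), L2 logistic regressions (C = 0.1, 1, 10) — by
leave-one-out cross-validated mean accuracy.  Inside each training fold,
features are z-scored and missing values replaced by fold means; the
held-out sample is transformed with training-fold statistics only.  A
feature constant within a fold standardizes to exactly zero and cannot
influence any prediction.

The bank members are hand-rolled deterministic solvers (exact k-NN with
smallest-index distance tie-break; damped-Newton logistic with unpenalized
intercept; hinge-loss SVM by cyclic dual coordinate descent with the bias
as a regularized constant feature).  Two reasons: the ranking contract
requires bit-reproducible tie-breaks, and exhaustive enumeration
(C(66,3) = 45 760 triples × 9 classifiers × 20 folds ≈ 8.6 million fits)
needs microsecond fits, which the numba-compiled kernels provide.  The
test suite cross-checks every member against its scikit-learn counterpart
(prediction agreement on random problems, and fold-by-fold LOOCV
equivalence on small tables).

Rankings sort by accuracy descending with deterministic tie-breaks (fewer
features, lexicographic feature names, bank order).  Exhaustive enumeration
is the default; a seeded subsample mode exists for larger registries.  No
multiple-testing correction is applied across combinations — the screen is
a ranking device, not an inference procedure, and any accuracy it reports
is optimistically biased by the maximum over thousands of combinations.

**Permutation null.**  Under label permutation the expected LOOCV accuracy
is *not* 0.5: leaving a sample out makes its class the training minority,
so majority-sensitive classifiers (logistic, SVM at weak signal) predict
the complement systematically — their null mean on 12 samples is ≈ 0.3 —
and 1-NN's exact null expectation is (n/2 − 1)/(n − 1) (0.4545 at n = 12).
The permutation tests therefore gate on the exact finite-fold expectation,
which approaches the idealized 0.5 as the cohort grows.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the measurement geometry (potential window, scan
rate, 1 Hz–1 kHz log-spaced EIS grid), paired before/after records, and a
class-dependent effect structure:

* **CV peaks** are exponentially modified Gaussians (EMG) per branch on a
  linear baseline, the tail pointing along the sweep past the peak, as
  diffusion produces in real voltammograms.  The EMG is height-normalized
  at its numerically located mode, so the configured peak potential and
  height are exact by construction and the analytic area is
  height/pdf(mode).  Defaults: anodic 0.30 V, cathodic 0.20 V, heights
  1.0e-5 A, σ = 0.05 V, asymmetry 1.0.  These are calibration knobs of the
  simulator, not measured values.
* **EIS** is the exact forward model of an equivalent circuit.  The default
  non-Faradaic cell places the electrode arc near 2.6 Hz and the layer arc
  near 1.6 kHz with a finite-length Warburg crossover (τ = 0.05 s) inside
  the band, so every parameter is identifiable from the 40-point spectrum.
* **LC effect** (applied to the "after" state of LC samples): CPE1-T
  divided by 30 (the centre of a 1–2 order-of-magnitude drop, ≈ 1.48
  orders), CPE2-T multiplied by 3, cathodic peak shifted +0.02 V,
  cathodic current attenuated 15%, peak asymmetry × 1.2.  H samples
  receive only small symmetric drift (5 mV potentials, 2% currents,
  5% CPE-T).
* **Noise**: additive Gaussian on CV current (1.5e-7 A ≈ 1.5% of peak
  height), independent multiplicative Gaussian (1%) on the real and
  imaginary parts of Z.  Inter-sensor variability: ±10 mV peak positions,
  ≈ 5% lognormal on currents, widths and circuit magnitudes.

Everything is driven by one seed through a `SeedSequence` spawn tree, so a
cohort is bit-reproducible.

What the generator does **not** emulate: Faradaic nonlinearity and
ohmic-drop distortion of CV peaks (no Butler–Volmer/Nicholson simulation),
electrode-geometry or diffusion-layer physics, drift within a measurement,
correlated (non-Gaussian) instrument noise, biological covariates (age,
sex, comorbidity), and any overlap structure between LC and H beyond the
configured effect-to-noise ratio.  Consequently, passing tests demonstrate
that the *pipeline* — extraction, fitting, table assembly, screening —
recovers a known planted signal under realistic noise; they say nothing
about how large that signal is in real plasma measurements.  With the
default effect sizes the cohort is strongly separable and the best pair
and triple accuracies saturate near 1.0, comfortably above the 0.70/0.73
regime reported for clinical data; shrinking the LC effect or raising the
noise in `CohortConfig` moves the screen into the partially-overlapping
regime.

## Numerical choices and degenerate inputs

* Trapezoidal integration everywhere an integral is needed; potential
  grids are uniform per segment (261 points per segment, 5 mV step, by
  default).
* Peak detection requires an interior extremum exceeding 3× a robust
  (MAD-based) noise floor estimated from the baseline window; strictly
  monotone segments raise a "no peak" error naming the branch.
* Half-height crossings are linearly interpolated; a missing crossing
  reports which side fell outside the window.
* `Incr` at P₀ = 0 yields NaN with a logged warning.
* LOOCV on a table with fewer than two samples per class is rejected (a
  training fold could otherwise contain one class; if it ever does, the
  fold predicts the majority class).
* Circuit-fit problem sizes: 40 frequency points (80 residuals) against
  5–10 free parameters; spectra shorter than the parameter count are
  rejected.
* The acceptance runs use 20-sample cohorts, 40-point spectra and the full
  C(66,2) + C(66,3) enumeration (≈ 4.3 × 10⁵ combination-classifier
  scores), which completes in a couple of minutes on one core.

## Known limitations

* The Rct/Warburg split of the low-frequency tail is poorly conditioned in
  a 3-decade window: with the 3-parameter generalized Warburg, Rct and W_R
  trade off under noise (medians ≈ 30–50% relative error at 1% noise).
  Recovery statistics are quoted for the semi-infinite variant (all
  parameter medians < 4%); fitted generalized-Warburg tails should be
  interpreted as a joint diffusion term, not element-wise.
* C_dl from the top half-decade is biased low when the Rs relaxation is
  in-band (see above).
* Screening accuracies are maxima over thousands of combinations and carry
  the corresponding selection optimism; they rank signal carriers, they do
  not estimate generalization error.
* The EIS decision rule assumes the M2 topology fits both states; fits that
  fail to converge yield an "indeterminate" call rather than a guess.
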