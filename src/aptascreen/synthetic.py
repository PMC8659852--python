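"""Synthetic electrochemistry generator for aptasensor pipeline testing.

Emulates the measurement campaign the analysis assumes: redox-probe cyclic
voltammograms recorded from −0.5 to 0.8 V at 0.03 V/s, non-Faradaic
impedance spectra over 1 Hz–1 kHz, and paired before/after-plasma
measurements for a lung-cancer (LC) versus healthy (H) cohort.

The CV peak model is an exponentially modified Gaussian (EMG) per sweep
branch on a linear baseline: the EMG's diffusional tail points along the
sweep direction past the maximum, matching the asymmetry of real
voltammetric peaks, and the peak is height-normalized at its mode so the
configured peak potential and height are exact by construction.  The EMG is
a unit-area density, so the analytic peak area is simply
``height / pdf(mode)``.

Impedance spectra are exact forward evaluations of an equivalent circuit
(see :mod:`aptascreen.impedance`) with independent multiplicative Gaussian
noise on the real and imaginary parts.  CV noise is additive Gaussian on
the current.

The class-dependent "after" effect mirrors the diagnostic signature the
screening stage is meant to detect: LC samples receive a drop of the
electrode-interface CPE1-T (default factor 30, i.e. about 1.5 orders of
magnitude), a rise of the biolayer CPE2-T, and cathodic-peak modifications
(potential shift, current attenuation, shape change); H samples receive
only small symmetric drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import exponnorm

from .impedance import CircuitSpec, ImpedanceSpectrum, circuit_impedance
from .voltammetry import Segment, Voltammogram

__all__ = [
    "CVShapeParams",
    "LCEffect",
    "HDrift",
    "NoiseConfig",
    "VariabilityConfig",
    "CohortConfig",
    "Measurement",
    "CohortRecord",
    "default_cv_shape",
    "default_faradaic_circuit",
    "default_nonfaradaic_circuit",
    "default_frequencies",
    "emg_peak",
    "emg_peak_area",
    "simulate_cv",
    "simulate_eis",
    "simulate_cohort",
    "simulate_coverage_pair",
]


@dataclass(frozen=True)
class CVShapeParams:
    """Generative parameters of one CV cycle.

    Peak currents are positive magnitudes (the cathodic current trace is
    negative but its height is stored positive); ``peak_width_scale`` is the
    Gaussian sigma of the EMG and ``peak_asymmetry`` the tail/sigma ratio
    (larger = heavier diffusional tail).
    """

    anodic_peak_potential: float = 0.30    # V
    cathodic_peak_potential: float = 0.20  # V
    anodic_peak_current: float = 1.0e-5    # A
    cathodic_peak_current: float = 1.0e-5  # A (positive magnitude)
    peak_width_scale: float = 0.05         # V
    peak_asymmetry: float = 1.0            # tail/sigma ratio
    baseline_slope: float = 1.0e-6         # A/V
    baseline_offset: float = 5.0e-7        # A
    noise_sd: float = 1.5e-7               # A

    def __post_init__(self) -> None:
        if not self.anodic_peak_potential > self.cathodic_peak_potential:
            raise ValueError(
                "anodic peak potential must exceed the cathodic one "
                "(classic redox-couple ordering)"
            )
        for name in ("anodic_peak_current", "cathodic_peak_current",
                     "peak_width_scale", "peak_asymmetry"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_cv_shape(**overrides) -> CVShapeParams:
    """Default redox-probe CV shape (calibration knobs, not measured data)."""
    return replace(CVShapeParams(), **overrides) if overrides else CVShapeParams()


def default_faradaic_circuit(**overrides) -> CircuitSpec:
    """Default modified Randles (M0) circuit for redox-probe EIS.

    CPE values are typical of an aptamer-modified gold disc electrode; the
    generalized-short Warburg gives the non-ideal in-band diffusion tail.
    """
    params = {
        "Rs": 100.0, "CPE_T": 4.2e-5, "CPE_P": 0.72, "Rct": 5000.0,
        "W_R": 3000.0, "W_tau": 0.05, "W_P": 0.45,
    }
    params.update(overrides)
    return CircuitSpec("M0_randles_w", params)


def default_nonfaradaic_circuit(**overrides) -> CircuitSpec:
    """Default non-Faradaic double-interface (M2) circuit.

    The first block (CPE1, Rp1) models the gold/solution double layer, the
    second (CPE2, Rp2, W) the aptamer-layer/solution boundary.
    """
    params = {
        "Rs": 150.0,
        "CPE1_T": 4.0e-5, "CPE1_P": 0.90, "Rp1": 2000.0,
        "CPE2_T": 5.0e-7, "CPE2_P": 0.85, "Rp2": 800.0,
        "W_R": 1500.0, "W_tau": 0.05, "W_P": 0.45,
    }
    params.update(overrides)
    return CircuitSpec("M2_nonfaradaic", params)


def default_frequencies(n_points: int = 40, f_min: float = 1.0,
                        f_max: float = 1000.0) -> np.ndarray:
    """Log-spaced EIS frequency grid, descending, 1 kHz to 1 Hz."""
    return np.logspace(np.log10(f_max), np.log10(f_min), n_points)


# ---------------------------------------------------------------------------
# EMG peak primitive
# ---------------------------------------------------------------------------

def _emg_mode(sigma: float, asymmetry: float) -> tuple[float, float]:
    """Location and density value of the EMG mode (loc=0, scale=sigma)."""
    K = asymmetry
    res = minimize_scalar(
        lambda x: -exponnorm.pdf(x, K, loc=0.0, scale=sigma),
        bounds=(-3.0 * sigma, (3.0 + 3.0 * K) * sigma),
        method="bounded",
        options={"xatol": 1e-12 * sigma},
    )
    return float(res.x), float(exponnorm.pdf(res.x, K, loc=0.0, scale=sigma))


def emg_peak(s: np.ndarray, s_peak: float, height: float, sigma: float,
             asymmetry: float) -> np.ndarray:
    """Height-normalized EMG evaluated on the sweep coordinate ``s``.

    The maximum equals ``height`` exactly at ``s = s_peak``; the tail decays
    toward larger ``s`` (past the peak, along the sweep).
    """
    mode, pdf_mode = _emg_mode(sigma, asymmetry)
    x = s - s_peak + mode
    return height * exponnorm.pdf(x, asymmetry, loc=0.0, scale=sigma) / pdf_mode


def emg_peak_area(height: float, sigma: float, asymmetry: float) -> float:
    """Analytic area of the height-normalized EMG peak.

    The underlying density integrates to one, so the area is
    ``height / pdf(mode)``.
    """
    _, pdf_mode = _emg_mode(sigma, asymmetry)
    return height / pdf_mode


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_cv(shape: CVShapeParams,
                window: tuple[float, float] = (-0.5, 0.8),
                scan_rate: float = 0.03,
                points_per_segment: int = 261,
                seed: int = 0) -> Voltammogram:
    """Generate one CV cycle: forward (anodic) and reverse (cathodic) sweep.

    Each segment is a linear baseline plus one EMG peak plus additive
    Gaussian current noise.  The anodic peak sits on the forward segment at
    the configured potential and height above baseline; the cathodic peak is
    a negative-current EMG on the reverse segment.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError("potential window must be non-degenerate")
    for name, ep in (("anodic", shape.anodic_peak_potential),
                     ("cathodic", shape.cathodic_peak_potential)):
        if not lo < ep < hi:
            raise ValueError(
                f"potential window [{lo}, {hi}] V excludes the {name} peak "
                f"at {ep} V"
            )
    if not scan_rate > 0:
        raise ValueError("scan rate must be strictly positive")
    if points_per_segment < 50:
        raise ValueError("need at least 50 points per segment")

    rng = np.random.default_rng(seed)
    E_fwd = np.linspace(lo, hi, points_per_segment)
    E_rev = np.linspace(hi, lo, points_per_segment)
    baseline_fwd = shape.baseline_slope * E_fwd + shape.baseline_offset
    baseline_rev = shape.baseline_slope * E_rev + shape.baseline_offset

    # forward sweep coordinate is the potential itself
    i_fwd = baseline_fwd + emg_peak(
        E_fwd, shape.anodic_peak_potential, shape.anodic_peak_current,
        shape.peak_width_scale, shape.peak_asymmetry,
    )
    # reverse sweep: ascending coordinate is -E; cathodic current is negative
    i_rev = baseline_rev - emg_peak(
        -E_rev, -shape.cathodic_peak_potential, shape.cathodic_peak_current,
        shape.peak_width_scale, shape.peak_asymmetry,
    )
    if shape.noise_sd > 0:
        i_fwd = i_fwd + rng.normal(0.0, shape.noise_sd, i_fwd.size)
        i_rev = i_rev + rng.normal(0.0, shape.noise_sd, i_rev.size)

    return Voltammogram(
        segments=[
            Segment(E_fwd, i_fwd, "forward"),
            Segment(E_rev, i_rev, "reverse"),
        ],
        scan_rate=scan_rate,
        metadata={"generator": "emg", "seed": int(seed)},
    )


def simulate_eis(circuit: CircuitSpec, frequencies=None,
                 noise_fraction: float = 0.0, seed: int = 0,
                 state: str = "before") -> ImpedanceSpectrum:
    """Generate an impedance spectrum from a circuit.

    Noise is multiplicative Gaussian applied to the real and imaginary parts
    independently; at ``noise_fraction = 0`` the spectrum equals the forward
    circuit model exactly.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if frequencies is None:
        frequencies = default_frequencies()
    spectrum = circuit_impedance(circuit, frequencies)
    z = spectrum.impedance
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        z = (z.real * (1.0 + rng.normal(0.0, noise_fraction, z.size))
             + 1j * z.imag * (1.0 + rng.normal(0.0, noise_fraction, z.size)))
    return ImpedanceSpectrum(frequencies=spectrum.frequencies, impedance=z,
                             state=state,
                             metadata={"topology": circuit.topology_id,
                                       "seed": int(seed)})


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LCEffect:
    """Effect of tumour-marker binding on an LC sample's 'after' state."""

    cpe1_drop_factor: float = 30.0        # CPE1-T divided by this (~1.5 orders)
    cpe2_rise_factor: float = 3.0         # CPE2-T multiplied by this
    cathodic_shift_V: float = 0.02        # cathodic peak potential shift
    cathodic_attenuation: float = 0.15    # fractional cathodic current loss
    cathodic_shape_factor: float = 1.2    # asymmetry multiplier

    def __post_init__(self) -> None:
        if not self.cpe1_drop_factor > 0 or not self.cpe2_rise_factor > 0:
            raise ValueError("effect factors must be positive")
        if not 0.0 <= self.cathodic_attenuation < 1.0:
            raise ValueError("cathodic_attenuation must lie in [0, 1)")


@dataclass(frozen=True)
class HDrift:
    """Small symmetric before/after drift applied to healthy samples."""

    potential_V: float = 0.005
    current_frac: float = 0.02
    cpe_frac: float = 0.05

    def __post_init__(self) -> None:
        if min(self.potential_V, self.current_frac, self.cpe_frac) < 0:
            raise ValueError("drift scales must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Instrument noise levels for both modalities."""

    cv_noise_sd: float = 1.5e-7        # A, additive
    eis_noise_fraction: float = 0.01   # multiplicative

    def __post_init__(self) -> None:
        if self.cv_noise_sd < 0 or self.eis_noise_fraction < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass(frozen=True)
class VariabilityConfig:
    """Inter-sensor (between-sample) variability of the baselines."""

    potential_sd_V: float = 0.01
    current_lognorm_sd: float = 0.05
    width_lognorm_sd: float = 0.05
    circuit_lognorm_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.potential_sd_V, self.current_lognorm_sd,
               self.width_lognorm_sd, self.circuit_lognorm_sd) < 0:
            raise ValueError("variability scales must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a synthetic LC/H cohort."""

    n_lc: int = 10
    n_h: int = 10
    seed: int = 1
    lc_effect: LCEffect = field(default_factory=LCEffect)
    h_drift: HDrift = field(default_factory=HDrift)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    variability: VariabilityConfig = field(default_factory=VariabilityConfig)
    base_shape: CVShapeParams = field(default_factory=CVShapeParams)
    base_circuit: CircuitSpec = field(default_factory=default_nonfaradaic_circuit)
    points_per_segment: int = 261
    window: tuple[float, float] = (-0.5, 0.8)
    scan_rate: float = 0.03
    n_frequencies: int = 40

    def __post_init__(self) -> None:
        if self.n_lc < 2 or self.n_h < 2:
            raise ValueError(
                "need at least 2 samples per class (LOOCV training folds "
                "must contain both classes)"
            )
        if self.base_circuit.topology_id != "M2_nonfaradaic":
            raise ValueError("cohort EIS baseline must be an M2 circuit")


@dataclass
class Measurement:
    """One state's paired CV + EIS measurement."""

    cv: Voltammogram
    eis: ImpedanceSpectrum


@dataclass
class CohortRecord:
    """One synthetic sample: paired before/after measurements plus the
    generating ground truth (for round-trip tests)."""

    sample_id: str
    label: str  # "LC" | "H"
    before: Measurement
    after: Measurement
    truth: dict


def _perturb_shape(shape: CVShapeParams, rng: np.random.Generator,
                   var: VariabilityConfig) -> CVShapeParams:
    """Draw one sensor's CV baseline from the population."""
    dEa = rng.normal(0.0, var.potential_sd_V)
    dEc = rng.normal(0.0, var.potential_sd_V)
    fIa = np.exp(rng.normal(0.0, var.current_lognorm_sd))
    fIc = np.exp(rng.normal(0.0, var.current_lognorm_sd))
    fw = np.exp(rng.normal(0.0, var.width_lognorm_sd))
    return replace(
        shape,
        anodic_peak_potential=shape.anodic_peak_potential + dEa,
        cathodic_peak_potential=shape.cathodic_peak_potential + dEc,
        anodic_peak_current=shape.anodic_peak_current * fIa,
        cathodic_peak_current=shape.cathodic_peak_current * fIc,
        peak_width_scale=shape.peak_width_scale * fw,
    )


def _perturb_circuit(circuit: CircuitSpec, rng: np.random.Generator,
                     var: VariabilityConfig) -> CircuitSpec:
    """Lognormal jitter on magnitudes (T's and R's); exponents stay fixed."""
    updates = {}
    for name, value in circuit.parameters.items():
        if name.endswith("_P"):
            updates[name] = value
        else:
            updates[name] = value * np.exp(
                rng.normal(0.0, var.circuit_lognorm_sd))
    return circuit.with_parameters(**updates)


def _apply_lc_effect(shape: CVShapeParams, circuit: CircuitSpec,
                     effect: LCEffect) -> tuple[CVShapeParams, CircuitSpec]:
    shape_after = replace(
        shape,
        cathodic_peak_potential=(shape.cathodic_peak_potential
                                 + effect.cathodic_shift_V),
        cathodic_peak_current=(shape.cathodic_peak_current
                               * (1.0 - effect.cathodic_attenuation)),
        peak_asymmetry=shape.peak_asymmetry * effect.cathodic_shape_factor,
    )
    circuit_after = circuit.with_parameters(
        CPE1_T=circuit["CPE1_T"] / effect.cpe1_drop_factor,
        CPE2_T=circuit["CPE2_T"] * effect.cpe2_rise_factor,
    )
    return shape_after, circuit_after


def _apply_h_drift(shape: CVShapeParams, circuit: CircuitSpec,
                   drift: HDrift,
                   rng: np.random.Generator) -> tuple[CVShapeParams, CircuitSpec]:
    if drift.potential_V == 0 and drift.current_frac == 0 and drift.cpe_frac == 0:
        return shape, circuit
    shape_after = replace(
        shape,
        anodic_peak_potential=(shape.anodic_peak_potential
                               + rng.normal(0.0, drift.potential_V)),
        cathodic_peak_potential=(shape.cathodic_peak_potential
                                 + rng.normal(0.0, drift.potential_V)),
        anodic_peak_current=(shape.anodic_peak_current
                             * (1.0 + rng.normal(0.0, drift.current_frac))),
        cathodic_peak_current=(shape.cathodic_peak_current
                               * (1.0 + rng.normal(0.0, drift.current_frac))),
    )
    updates = {}
    for name, value in circuit.parameters.items():
        if name.endswith("_T"):
            updates[name] = value * (1.0 + rng.normal(0.0, drift.cpe_frac))
    circuit_after = circuit.with_parameters(**updates) if updates else circuit
    return shape_after, circuit_after


def simulate_cohort(config: CohortConfig) -> list:
    """Generate a labelled before/after cohort of paired CV+EIS records.

    Each sample draws its own CV shape and circuit from the population
    baselines (inter-sensor variability); the 'after' state applies the LC
    effect to LC samples and only symmetric drift to H samples.  Fully
    reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    labels = ["LC"] * config.n_lc + ["H"] * config.n_h
    children = ss.spawn(len(labels))
    frequencies = default_frequencies(config.n_frequencies)
    records: list[CohortRecord] = []

    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        shape0 = _perturb_shape(config.base_shape, rng, config.variability)
        shape0 = replace(shape0, noise_sd=config.noise.cv_noise_sd)
        circuit0 = _perturb_circuit(config.base_circuit, rng,
                                    config.variability)
        if label == "LC":
            shape1, circuit1 = _apply_lc_effect(shape0, circuit0,
                                                config.lc_effect)
        else:
            shape1, circuit1 = _apply_h_drift(shape0, circuit0,
                                              config.h_drift, rng)
        seeds = rng.integers(0, 2**31 - 1, size=4)
        before = Measurement(
            cv=simulate_cv(shape0, config.window, config.scan_rate,
                           config.points_per_segment, seed=int(seeds[0])),
            eis=simulate_eis(circuit0, frequencies,
                             config.noise.eis_noise_fraction,
                             seed=int(seeds[1]), state="before"),
        )
        after = Measurement(
            cv=simulate_cv(shape1, config.window, config.scan_rate,
                           config.points_per_segment, seed=int(seeds[2])),
            eis=simulate_eis(circuit1, frequencies,
                             config.noise.eis_noise_fraction,
                             seed=int(seeds[3]), state="after"),
        )
        records.append(CohortRecord(
            sample_id=f"{label}{i + 1:02d}",
            label=label,
            before=before,
            after=after,
            truth={
                "shape_before": shape0, "shape_after": shape1,
                "circuit_before": circuit0, "circuit_after": circuit1,
            },
        ))
    return records


def simulate_coverage_pair(coverage_percent: float,
                           base_shape: CVShapeParams | None = None,
                           seed: int = 0,
                           **cv_kwargs) -> tuple[Voltammogram, Voltammogram]:
    """Bare/modified CV pair whose anodic peak area ratio encodes a known
    surface coverage: ``S_after = (1 - coverage/100) * S_before`` (noise
    aside)."""
    if not 0.0 <= coverage_percent < 100.0:
        raise ValueError(
            "coverage must lie in [0, 100): a fully blocked electrode has "
            "no measurable oxidation peak"
        )
    if base_shape is None:
        base_shape = default_cv_shape()
    factor = 1.0 - coverage_percent / 100.0
    shape_after = replace(
        base_shape,
        anodic_peak_current=base_shape.anodic_peak_current * factor,
    )
    before = simulate_cv(base_shape, seed=seed, **cv_kwargs)
    after = simulate_cv(shape_after, seed=seed + 1, **cv_kwargs)
    return before, after
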