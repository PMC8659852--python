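"""Cyclic-voltammogram parsing and peak-feature extraction.

A cyclic voltammogram (CV) is stored as two sweep segments: a forward
(ascending-potential) branch carrying the redox-probe oxidation (anodic)
peak and a reverse (descending) branch carrying the reduction (cathodic)
peak.  Each branch is reduced to a peak descriptor — peak potential and
baseline-corrected height, onset potential/current, full width at half
maximum, a left/right half-width shape ratio, and the baseline-corrected
peak area — from which the derived scalars dE = |Ea - Ec|, the current and
area ratios R_I = Ia/Ic and R_S = Sa/Sc, and the half-wave potential
E_half = (Ea + Ec)/2 follow.

The baseline under each peak is a least-squares line through the leading
(approach-side) fraction of the segment, the conventional tangent method.
Peak heights and areas are magnitudes, so ratios are positive.

Surface coverage of a blocking layer is quantified from the attenuation of
the anodic peak area between a bare and a modified electrode:
``coverage = (1 - S_after/S_before) * 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Segment",
    "Voltammogram",
    "PeakDescriptor",
    "CVFeatures",
    "NoPeakError",
    "estimate_baseline",
    "find_peak",
    "peak_onset",
    "peak_width_shape",
    "peak_area",
    "extract_segment_peak",
    "extract_cv_features",
    "surface_coverage",
    "CV_FEATURE_NAMES",
]

#: fixed export order of the CV feature vector
CV_FEATURE_NAMES = (
    "Ea", "Ec", "Einit_a", "Einit_c", "dE", "Ew_a", "Ew_c", "Esh_a",
    "Esh_c", "Ia", "Ic", "Iinit_a", "Iinit_c", "Sa", "Sc", "R_I", "R_S",
    "E_half",
)


class NoPeakError(ValueError):
    """Raised when a sweep segment contains no detectable peak."""


@dataclass
class Segment:
    """One potential sweep: monotone potential grid with its current trace."""

    potential: np.ndarray  # V
    current: np.ndarray    # A
    direction: str         # "forward" (ascending) or "reverse" (descending)

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got "
                             f"{self.direction!r}")
        if self.potential.shape != self.current.shape:
            raise ValueError("potential and current arrays differ in length")
        if self.potential.size < 10:
            raise ValueError("segment needs at least 10 points")
        dE = np.diff(self.potential)
        if self.direction == "forward" and not np.all(dE > 0):
            raise ValueError("forward segment potential must strictly ascend")
        if self.direction == "reverse" and not np.all(dE < 0):
            raise ValueError("reverse segment potential must strictly descend")

    @property
    def grid_step(self) -> float:
        return float(np.abs(np.median(np.diff(self.potential))))


@dataclass
class Voltammogram:
    """A CV cycle: ordered sweep segments plus scan metadata."""

    segments: list
    scan_rate: float = 0.03  # V/s
    metadata: dict = field(default_factory=dict)

    def segment(self, direction: str) -> Segment:
        for seg in self.segments:
            if seg.direction == direction:
                return seg
        raise ValueError(f"no {direction} segment present")

    @property
    def forward(self) -> Segment:
        return self.segment("forward")

    @property
    def reverse(self) -> Segment:
        return self.segment("reverse")


@dataclass
class PeakDescriptor:
    """Per-branch peak quantities (heights/areas as positive magnitudes)."""

    branch: str      # "anodic" | "cathodic"
    E_peak: float    # V
    I_peak: float    # A, baseline-corrected magnitude
    E_init: float    # V, onset potential
    I_init: float    # A, raw current at onset
    E_w: float       # V, FWHM
    E_sh: float      # left/right half-width ratio (sweep direction)
    S: float         # A*V, baseline-corrected area


@dataclass
class CVFeatures:
    """Both peak descriptors plus the derived scalar identities."""

    anodic: PeakDescriptor
    cathodic: PeakDescriptor
    delta_E: float
    R_I: float
    R_S: float
    E_half: float

    def as_dict(self) -> dict[str, float]:
        a, c = self.anodic, self.cathodic
        return {
            "Ea": a.E_peak, "Ec": c.E_peak,
            "Einit_a": a.E_init, "Einit_c": c.E_init,
            "dE": self.delta_E,
            "Ew_a": a.E_w, "Ew_c": c.E_w,
            "Esh_a": a.E_sh, "Esh_c": c.E_sh,
            "Ia": a.I_peak, "Ic": c.I_peak,
            "Iinit_a": a.I_init, "Iinit_c": c.I_init,
            "Sa": a.S, "Sc": c.S,
            "R_I": self.R_I, "R_S": self.R_S, "E_half": self.E_half,
        }


# ---------------------------------------------------------------------------
# per-segment primitives
# ---------------------------------------------------------------------------

def estimate_baseline(segment: Segment,
                      pre_peak_fraction: float = 0.2) -> tuple[float, float]:
    """Least-squares linear baseline through the leading (approach-side)
    ``pre_peak_fraction`` of the segment.

    Returns ``(slope A/V, intercept A)``.
    """
    if not 0.0 < pre_peak_fraction <= 0.5:
        raise ValueError("pre_peak_fraction must lie in (0, 0.5]")
    n = segment.potential.size
    n_base = int(np.floor(pre_peak_fraction * n))
    if n_base < 5:
        raise ValueError(
            f"baseline window has {n_base} points; need at least 5"
        )
    E = segment.potential[:n_base]
    I = segment.current[:n_base]
    slope, intercept = np.polyfit(E, I, 1)
    return float(slope), float(intercept)


def _corrected(segment: Segment, baseline: tuple[float, float]) -> np.ndarray:
    slope, intercept = baseline
    return segment.current - (slope * segment.potential + intercept)


def _peak_sign(segment: Segment) -> float:
    # anodic (oxidation, positive current) on the forward sweep; cathodic
    # (reduction, negative current) on the reverse sweep
    return 1.0 if segment.direction == "forward" else -1.0


def find_peak(segment: Segment, baseline: tuple[float, float],
              snr_floor: float = 3.0) -> tuple[float, float]:
    """Locate the branch's peak on the baseline-corrected current.

    Returns ``(E_peak, I_peak)`` with ``I_peak`` the corrected magnitude.
    The extremum must be interior and exceed ``snr_floor`` times a robust
    noise scale estimated from the baseline-window residuals.
    """
    corr = _corrected(segment, baseline) * _peak_sign(segment)
    idx = int(np.argmax(corr))
    if idx == 0 or idx == corr.size - 1:
        raise NoPeakError(
            f"no interior extremum on the {segment.direction} segment"
        )
    n_base = max(int(0.2 * corr.size), 5)
    resid = corr[:n_base]
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if corr[idx] <= snr_floor * noise or corr[idx] <= 0:
        raise NoPeakError(
            f"candidate extremum on the {segment.direction} segment does not "
            f"clear the signal-to-noise floor"
        )
    return float(segment.potential[idx]), float(corr[idx])


def _peak_index(segment: Segment, E_peak: float) -> int:
    return int(np.argmin(np.abs(segment.potential - E_peak)))


def peak_onset(segment: Segment, baseline: tuple[float, float],
               peak: tuple[float, float],
               threshold_fraction: float = 0.05) -> tuple[float, float]:
    """Onset of the peak: first potential, sweeping toward the peak, where
    the corrected magnitude exceeds ``threshold_fraction * I_peak`` and stays
    above it up to the peak.  Returns ``(E_init, raw current there)``.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    E_peak, I_peak = peak
    corr = _corrected(segment, baseline) * _peak_sign(segment)
    ip = _peak_index(segment, E_peak)
    thr = threshold_fraction * I_peak
    below = np.nonzero(corr[: ip + 1] < thr)[0]
    onset = int(below[-1]) + 1 if below.size else 0
    if onset > ip:
        raise NoPeakError("onset threshold never crossed before the peak")
    return float(segment.potential[onset]), float(segment.current[onset])


def peak_width_shape(segment: Segment, baseline: tuple[float, float],
                     peak: tuple[float, float]) -> tuple[float, float]:
    """FWHM and half-width shape ratio of the baseline-corrected peak.

    ``E_w`` is the full width at half the corrected height; ``E_sh`` the
    approach-side half-width divided by the trailing-side half-width, both
    taken in sweep direction, so a peak with a heavy diffusional tail past
    the maximum has ``E_sh < 1`` and a symmetric peak has ``E_sh = 1``.
    Half-height crossings are linearly interpolated.
    """
    E_peak, I_peak = peak
    corr = _corrected(segment, baseline) * _peak_sign(segment)
    ip = _peak_index(segment, E_peak)
    half = 0.5 * I_peak
    # sweep coordinate: ascending along the sweep for both directions
    s = segment.potential if segment.direction == "forward" \
        else -segment.potential

    def cross(i_lo: int, i_hi: int) -> float:
        f = (half - corr[i_lo]) / (corr[i_hi] - corr[i_lo])
        return float(s[i_lo] + f * (s[i_hi] - s[i_lo]))

    left = None
    for i in range(ip, 0, -1):
        if corr[i - 1] < half <= corr[i]:
            left = cross(i - 1, i)
            break
    right = None
    for i in range(ip, corr.size - 1):
        if corr[i] >= half > corr[i + 1]:
            right = cross(i + 1, i)
            break
    if left is None or right is None:
        missing = []
        if left is None:
            missing.append("approach-side")
        if right is None:
            missing.append("trailing-side")
        raise NoPeakError(
            f"half-height crossing outside the recorded window "
            f"({' and '.join(missing)}) on the {segment.direction} segment"
        )
    s_peak = float(s[ip])
    E_w = right - left
    E_sh = (s_peak - left) / (right - s_peak)
    return float(E_w), float(E_sh)


def peak_area(segment: Segment, baseline: tuple[float, float],
              peak: tuple[float, float],
              threshold_fraction: float = 0.05) -> float:
    """Trapezoidal area of the baseline-corrected peak (A*V).

    Integration runs from the onset crossing to the symmetric trailing
    crossing, i.e. over the region where the corrected magnitude stays above
    ``threshold_fraction * I_peak`` around the maximum.
    """
    E_peak, I_peak = peak
    corr = _corrected(segment, baseline) * _peak_sign(segment)
    ip = _peak_index(segment, E_peak)
    thr = threshold_fraction * I_peak
    below_pre = np.nonzero(corr[: ip + 1] < thr)[0]
    lo = int(below_pre[-1]) + 1 if below_pre.size else 0
    below_post = np.nonzero(corr[ip:] < thr)[0]
    hi = ip + int(below_post[0]) - 1 if below_post.size else corr.size - 1
    if hi <= lo:
        raise NoPeakError("empty integration window")
    window = slice(lo, hi + 1)
    area = np.trapezoid(corr[window], segment.potential[window])
    area = abs(float(area))
    if not area > 0:
        raise NoPeakError("non-positive peak area")
    return area


def extract_segment_peak(segment: Segment, *,
                         baseline_fraction: float = 0.2,
                         onset_fraction: float = 0.05) -> PeakDescriptor:
    """Run the full per-branch pipeline and return the peak descriptor."""
    branch = "anodic" if segment.direction == "forward" else "cathodic"
    try:
        baseline = estimate_baseline(segment, baseline_fraction)
        peak = find_peak(segment, baseline)
        E_init, I_init = peak_onset(segment, baseline, peak, onset_fraction)
        E_w, E_sh = peak_width_shape(segment, baseline, peak)
        S = peak_area(segment, baseline, peak, onset_fraction)
    except (NoPeakError, ValueError) as err:
        raise NoPeakError(f"{branch} branch: {err}") from err
    return PeakDescriptor(branch=branch, E_peak=peak[0], I_peak=peak[1],
                          E_init=E_init, I_init=I_init, E_w=E_w, E_sh=E_sh,
                          S=S)


def extract_cv_features(cv: Voltammogram, *,
                        baseline_fraction: float = 0.2,
                        onset_fraction: float = 0.05) -> CVFeatures:
    """Extract the full CV feature set from one voltammogram."""
    anodic = extract_segment_peak(cv.forward,
                                  baseline_fraction=baseline_fraction,
                                  onset_fraction=onset_fraction)
    cathodic = extract_segment_peak(cv.reverse,
                                    baseline_fraction=baseline_fraction,
                                    onset_fraction=onset_fraction)
    return CVFeatures(
        anodic=anodic,
        cathodic=cathodic,
        delta_E=abs(anodic.E_peak - cathodic.E_peak),
        R_I=anodic.I_peak / cathodic.I_peak,
        R_S=anodic.S / cathodic.S,
        E_half=0.5 * (anodic.E_peak + cathodic.E_peak),
    )


def surface_coverage(cv_before: Voltammogram, cv_after: Voltammogram, *,
                     use: str = "area",
                     baseline_fraction: float = 0.2,
                     onset_fraction: float = 0.05) -> float:
    """Blocking-layer surface coverage (%) from anodic-peak attenuation.

    ``coverage = (1 - after/before) * 100`` on the oxidation-peak area
    (``use="area"``, the default) or height (``use="height"``).  A negative
    value (peak grew after modification) is physically odd and triggers a
    warning but is returned as-is.
    """
    if use not in ("area", "height"):
        raise ValueError("use must be 'area' or 'height'")
    peaks = []
    for cv in (cv_before, cv_after):
        desc = extract_segment_peak(cv.forward,
                                    baseline_fraction=baseline_fraction,
                                    onset_fraction=onset_fraction)
        peaks.append(desc.S if use == "area" else desc.I_peak)
    coverage = (1.0 - peaks[1] / peaks[0]) * 100.0
    if coverage < 0:
        warnings.warn(
            f"negative surface coverage ({coverage:.2f}%): the oxidation "
            f"peak grew after modification"
        )
    return float(coverage)
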