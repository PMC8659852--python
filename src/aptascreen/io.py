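"""File dialects: voltammogram/spectrum CSV, cohort manifest, fit JSON.

Plain-text formats only:

* voltammogram CSV — header ``potential_V,current_A,segment`` with
  ``segment`` in {forward, reverse}, one row per point, '.' decimal;
* spectrum CSV — header ``freq_Hz,z_re_ohm,z_im_ohm``, descending frequency;
* cohort manifest JSON — a list of
  ``{sample_id, label, before: {cv_path, eis_path}, after: {...}}`` with
  paths relative to the manifest location;
* fit JSON — ``{topology, params: {name: {value, stderr}}, chi_square,
  aic, converged}``.
"""

from __future__ import annotations

import json
import pandas as pd

from .impedance import CircuitSpec, FitResult, ImpedanceSpectrum
from .voltammetry import Segment, Voltammogram

__all__ = [
    "write_voltammogram_csv", "read_voltammogram_csv",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_cohort_manifest", "read_cohort_manifest",
    "write_fit_json", "read_fit_json",
]

CV_HEADER = ["potential_V", "current_A", "segment"]
EIS_HEADER = ["freq_Hz", "z_re_ohm", "z_im_ohm"]


def write_voltammogram_csv(cv: Voltammogram, path) -> None:
    frames = []
    for seg in cv.segments:
        frames.append(pd.DataFrame({
            "potential_V": seg.potential,
            "current_A": seg.current,
            "segment": seg.direction,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_voltammogram_csv(path, scan_rate: float = 0.03) -> Voltammogram:
    df = pd.read_csv(path)
    if list(df.columns) != CV_HEADER:
        raise ValueError(
            f"{path}: expected columns {CV_HEADER}, got {list(df.columns)}"
        )
    segments = []
    for direction in ("forward", "reverse"):
        part = df[df["segment"] == direction]
        if len(part):
            segments.append(Segment(
                part["potential_V"].to_numpy(dtype=float),
                part["current_A"].to_numpy(dtype=float),
                direction,
            ))
    if not segments:
        raise ValueError(f"{path}: no forward/reverse segments found")
    return Voltammogram(segments=segments, scan_rate=scan_rate,
                        metadata={"source": str(path)})


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    pd.DataFrame({
        "freq_Hz": spectrum.frequencies,
        "z_re_ohm": spectrum.impedance.real,
        "z_im_ohm": spectrum.impedance.imag,
    }).to_csv(path, index=False)


def read_spectrum_csv(path, state: str = "before") -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    if list(df.columns) != EIS_HEADER:
        raise ValueError(
            f"{path}: expected columns {EIS_HEADER}, got {list(df.columns)}"
        )
    z = df["z_re_ohm"].to_numpy(dtype=float) \
        + 1j * df["z_im_ohm"].to_numpy(dtype=float)
    return ImpedanceSpectrum(
        frequencies=df["freq_Hz"].to_numpy(dtype=float),
        impedance=z, state=state, metadata={"source": str(path)},
    )


def write_cohort_manifest(entries: list, path) -> None:
    """``entries``: list of {sample_id, label, before/after: {cv_path,
    eis_path}} with paths relative to the manifest's directory."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cohort_manifest(path) -> list:
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a JSON list")
    for e in entries:
        for key in ("sample_id", "label", "before", "after"):
            if key not in e:
                raise ValueError(f"{path}: manifest entry missing {key!r}")
    return entries


def write_fit_json(fit: FitResult, path) -> None:
    payload = {
        "topology": fit.circuit.topology_id,
        "warburg_variant": fit.circuit.warburg_variant,
        "params": {
            name: {"value": float(value),
                   "stderr": float(fit.uncertainties.get(name, float("nan")))}
            for name, value in fit.circuit.parameters.items()
        },
        "chi_square": fit.chi_square,
        "aic": fit.aic,
        "n_points": fit.n_points,
        "converged": bool(fit.converged),
        "weighting": fit.weighting,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_fit_json(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    circuit = CircuitSpec(
        payload["topology"],
        {k: v["value"] for k, v in payload["params"].items()},
        warburg_variant=payload.get("warburg_variant", "generalized_short"),
    )
    return FitResult(
        circuit=circuit,
        uncertainties={k: v["stderr"] for k, v in payload["params"].items()},
        chi_square=payload["chi_square"],
        n_points=payload["n_points"],
        converged=payload["converged"],
        aic=payload["aic"],
        weighting=payload.get("weighting", "modulus"),
    )
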