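"""End-to-end pipeline: simulate → extract → fit → build-table → screen.

One :class:`RunConfig` describes a whole reproducible run: cohort design,
extractor settings, circuit-fit settings and screening plan.  Stages write
their outputs into the run directory using the package's plain-text
dialects, a :class:`RunManifest` records every artifact with its SHA-256
checksum, and reruns with the same config and seed reproduce the feature
table and screen rankings byte for byte.

``--resume`` semantics: a stage is skipped when all of its declared outputs
already exist and no upstream stage was re-executed; deleting an
intermediate file therefore regenerates that stage and everything
downstream, nothing else.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from . import __version__
from .features import (BASE_SETS, FeatureTable, build_feature_table,
                       extract_sample_record)
from .impedance import CircuitSpec, eis_decision_rule, fit_circuit
from .screening import screen_combinations, summarize_screen
from .synthetic import (CohortConfig, CVShapeParams, HDrift, LCEffect,
                        NoiseConfig, VariabilityConfig,
                        default_nonfaradaic_circuit, simulate_cohort)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline",
           "validate_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    baseline_fraction: float = 0.2
    onset_fraction: float = 0.05
    fit_enabled: bool = True
    fit_topology: str = "M2_nonfaradaic"
    fit_weighting: str = "modulus"
    screen_sizes: tuple = (2, 3)
    base_set: str = "full"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.base_set not in BASE_SETS:
            raise ValueError(f"unknown base_set {self.base_set!r}")
        self.screen_sizes = tuple(int(s) for s in self.screen_sizes)
        if any(s < 1 or s > 3 for s in self.screen_sizes):
            raise ValueError("screen sizes must be in {1, 2, 3}")
        # the run seed overrides the cohort seed so one knob controls all
        # randomness
        if self.cohort.seed != self.seed:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, CircuitSpec):
                return {"topology_id": obj.topology_id,
                        "parameters": dict(obj.parameters),
                        "warburg_variant": obj.warburg_variant}
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        cohort_data = dict(data.pop("cohort", {}))
        sub = {}
        for key, sub_cls in (("lc_effect", LCEffect), ("h_drift", HDrift),
                             ("noise", NoiseConfig),
                             ("variability", VariabilityConfig),
                             ("base_shape", CVShapeParams)):
            if key in cohort_data:
                sub[key] = sub_cls(**cohort_data.pop(key))
        if "base_circuit" in cohort_data:
            bc = cohort_data.pop("base_circuit")
            sub["base_circuit"] = CircuitSpec(
                bc["topology_id"], bc["parameters"],
                warburg_variant=bc.get("warburg_variant",
                                       "generalized_short"))
        if "window" in cohort_data:
            cohort_data["window"] = tuple(cohort_data["window"])
        cohort = CohortConfig(**cohort_data, **sub)
        return cls(cohort=cohort, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Artifacts of a completed run with checksums for provenance."""

    out_dir: str
    seed: int
    version: str
    started: str
    finished: str
    files: dict  # relative path -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def verify(self, out_dir=None) -> list:
        """Return a list of (path, problem) for missing/modified files."""
        root = Path(out_dir or self.out_dir)
        problems = []
        for rel, digest in self.files.items():
            p = root / rel
            if not p.exists():
                problems.append((rel, "missing"))
            elif _sha256(p) != digest:
                problems.append((rel, "checksum mismatch"))
        return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _outputs_exist(paths) -> bool:
    return all(Path(p).exists() for p in paths)


def run_pipeline(config: RunConfig, out_dir, resume: bool = False) -> RunManifest:
    """Execute all stages into ``out_dir`` and return the manifest.

    Any stage failure writes a ``FAILED`` marker naming the stage (partial
    outputs are kept for inspection) and raises :class:`PipelineError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    config.to_yaml(out / "config.yaml")
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    tracked: list[Path] = [out / "config.yaml"]
    stage = "simulate"
    try:
        # ---- simulate ---------------------------------------------------
        data_dir = out / "data"
        manifest_path = out / "cohort.json"
        n = config.cohort.n_lc + config.cohort.n_h
        expected = [manifest_path] + [
            data_dir / f"{sid}_{st}_{kind}.csv"
            for sid in range(n) for st in ("before", "after")
            for kind in ("cv", "eis")
        ]
        ran_simulate = not (resume and _outputs_exist([manifest_path]))
        if ran_simulate:
            data_dir.mkdir(exist_ok=True)
            records = simulate_cohort(config.cohort)
            entries = []
            for rec in records:
                entry = {"sample_id": rec.sample_id, "label": rec.label}
                for st in ("before", "after"):
                    meas = getattr(rec, st)
                    cv_rel = f"data/{rec.sample_id}_{st}_cv.csv"
                    eis_rel = f"data/{rec.sample_id}_{st}_eis.csv"
                    aio.write_voltammogram_csv(meas.cv, out / cv_rel)
                    aio.write_spectrum_csv(meas.eis, out / eis_rel)
                    entry[st] = {"cv_path": cv_rel, "eis_path": eis_rel}
                entries.append(entry)
            aio.write_cohort_manifest(entries, manifest_path)
            logger.info("simulate: %d samples -> %s", len(entries), data_dir)
        entries = aio.read_cohort_manifest(manifest_path)
        tracked.append(manifest_path)
        tracked += [out / e[st][k] for e in entries for st in ("before", "after")
                    for k in ("cv_path", "eis_path")]

        # ---- extract + build-table --------------------------------------
        stage = "extract"
        table_path = out / "table.csv"
        ran_table = ran_simulate or not (resume and _outputs_exist([table_path]))
        if ran_table:
            frecs = []
            for e in entries:
                kwargs = {}
                for st in ("before", "after"):
                    kwargs[f"cv_{st}"] = aio.read_voltammogram_csv(
                        out / e[st]["cv_path"], config.cohort.scan_rate)
                    kwargs[f"eis_{st}"] = aio.read_spectrum_csv(
                        out / e[st]["eis_path"], state=st)
                frecs.append(extract_sample_record(
                    e["sample_id"], e["label"],
                    baseline_fraction=config.baseline_fraction,
                    onset_fraction=config.onset_fraction, **kwargs))
            stage = "build-table"
            table = build_feature_table(frecs, config.base_set)
            table.to_csv(table_path)
            logger.info("build-table: %d rows x %d features",
                        len(table), len(table.feature_names))
        else:
            table = FeatureTable.from_csv(table_path, config.base_set)
        tracked.append(table_path)

        # ---- fit (decision-rule path) -----------------------------------
        stage = "fit"
        fits_path = out / "fits.json"
        if config.fit_enabled:
            ran_fit = ran_simulate or not (resume and _outputs_exist([fits_path]))
            if ran_fit:
                decisions = []
                for e in entries:
                    fits = {}
                    for st in ("before", "after"):
                        sp = aio.read_spectrum_csv(out / e[st]["eis_path"],
                                                   state=st)
                        fits[st] = fit_circuit(sp, config.fit_topology,
                                               weighting=config.fit_weighting)
                    decision = eis_decision_rule(fits["before"], fits["after"])
                    decisions.append({
                        "sample_id": e["sample_id"],
                        "label": e["label"],
                        "call": decision.call,
                        "log10_cpe1_drop": decision.log10_cpe1_drop,
                        "cpe2_rise": decision.cpe2_rise,
                        "chi_square": {st: fits[st].chi_square
                                       for st in fits},
                    } if config.fit_topology == "M2_nonfaradaic" else {
                        "sample_id": e["sample_id"],
                        "label": e["label"],
                        "chi_square": {st: fits[st].chi_square
                                       for st in fits},
                    })
                with open(fits_path, "w") as fh:
                    json.dump(decisions, fh, indent=1, sort_keys=True)
                    fh.write("\n")
                logger.info("fit: %d before/after pairs", len(entries))
            tracked.append(fits_path)

        # ---- screen -----------------------------------------------------
        stage = "screen"
        report = {}
        for size in config.screen_sizes:
            screen_path = out / f"screen_size{size}.json"
            ran_screen = ran_table or not (resume
                                           and _outputs_exist([screen_path]))
            if ran_screen:
                results = screen_combinations(table, size)
                payload = {
                    "subset_size": size,
                    "summary": summarize_screen(results),
                    "results": [
                        {"features": list(r.features), "family": r.family,
                         "hyperparameter": r.hyperparameter,
                         "accuracy": r.accuracy}
                        for r in results.itertuples()
                    ],
                }
                with open(screen_path, "w") as fh:
                    json.dump(payload, fh, indent=1, sort_keys=True)
                    fh.write("\n")
                report[size] = payload["summary"]
                logger.info("screen size %d: max accuracy %.3f", size,
                            report[size]["max_accuracy"])
            tracked.append(screen_path)
    except Exception as err:
        failed_marker.write_text(f"stage: {stage}\nerror: {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err

    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest = RunManifest(
        out_dir=str(out),
        seed=config.seed,
        version=__version__,
        started=started,
        finished=finished,
        files={str(p.relative_to(out)): _sha256(p) for p in tracked
               if p.exists()},
    )
    manifest.to_json(out / "run_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(path) -> list:
    """Validate a data file against its dialect rules.

    The file kind is sniffed from the header/extension.  Returns a list of
    violation dicts ``{"rule": ..., "message": ...}``; an empty list means
    the file is valid.  Unreadable files raise ``OSError``.
    """
    p = Path(path)
    if not p.exists():
        raise OSError(f"{path}: no such file")
    violations: list[dict] = []

    def add(rule: str, message: str) -> None:
        violations.append({"rule": rule, "message": message})

    if p.suffix == ".json":
        try:
            aio.read_cohort_manifest(p)
        except (ValueError, json.JSONDecodeError) as err:
            add("manifest", str(err))
        return violations

    try:
        header = pd.read_csv(p, nrows=0).columns.tolist()
    except Exception as err:
        raise OSError(f"{path}: unreadable ({err})") from err

    if header == aio.CV_HEADER:
        df = pd.read_csv(p)
        for direction in ("forward", "reverse"):
            part = df[df["segment"] == direction]
            if len(part) == 0:
                add("segments", f"missing {direction} segment")
                continue
            dE = np.diff(part["potential_V"].to_numpy(dtype=float))
            ok = np.all(dE > 0) if direction == "forward" else np.all(dE < 0)
            if not ok:
                add("monotone", f"{direction} segment not monotone")
            if len(part) < 10:
                add("length", f"{direction} segment has {len(part)} points "
                              f"(need >= 10)")
        bad = set(df["segment"]) - {"forward", "reverse"}
        if bad:
            add("segment-values", f"unknown segment value(s) {sorted(bad)}")
    elif header == aio.EIS_HEADER:
        df = pd.read_csv(p)
        f = df["freq_Hz"].to_numpy(dtype=float)
        for i, fi in enumerate(f):
            if fi <= 0:
                add("positivity", f"row {i + 2}: frequency {fi} Hz must be "
                                  f"strictly positive")
        if np.any(np.diff(f) >= 0):
            add("order", "frequencies must be strictly descending")
        if len(df) < 8:
            add("length", f"spectrum has {len(df)} points (need >= 8)")
    else:
        add("header", f"unrecognized header {header}; expected "
                      f"{aio.CV_HEADER} or {aio.EIS_HEADER}")
    return violations
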