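"""CSV/JSON readers, writers, and machine-readable run reports.

File contracts
--------------
Time series: comma-separated, UTF-8, dot decimal, mandatory header; first
column ``time_s``, one column per metabolite (units encoded in names).
Spectra: delimited matrix whose first row is the ppm axis and each further
row one spectrum, plus a JSON metadata sidecar.  Parameters: JSON objects
with ``kinetic`` / ``acquisition`` blocks.  Reports: JSON with stable key
order, embedding the resolved configuration, seed, package version and an
SHA-256 hash of every input file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .models import (
    LABEL_SYNONYMS,
    AcquisitionParameters,
    KineticParameters,
    MetaboliteTimeSeries,
)
from .synthetic import PeakShape, SpectraStack

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_parameters",
    "write_parameters",
    "write_spectra",
    "read_spectra",
    "build_report",
    "write_report",
]


def _normalise_label(raw: str) -> str:
    key = raw.strip().lower()
    return LABEL_SYNONYMS.get(key, key)


def read_timeseries(path) -> MetaboliteTimeSeries:
    """Read a metabolite time-series CSV.

    Validates a strictly increasing, finite time grid (named errors point
    at the offending row/column), normalises metabolite labels to the
    canonical set, and rejects duplicate labels.  Grid uniformity is
    checked at 1e-6 relative tolerance but non-uniform grids are accepted
    (downstream sum-based AUC will demand the trapezoidal mode).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValidationError(f"{path.name}: missing required column 'time_s'")
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{path.name}: NaN in column {col!r} at row {row}")
    times = df["time_s"].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise ValidationError(
            f"{path.name}: time_s not strictly increasing at row {row}"
        )
    signals = {}
    for col in df.columns:
        if col == "time_s":
            continue
        label = _normalise_label(col)
        if label in signals:
            raise ValidationError(f"{path.name}: duplicate metabolite column {label!r}")
        signals[label] = df[col].to_numpy(dtype=float)
    if not signals:
        raise ValidationError(f"{path.name}: no metabolite columns")
    return MetaboliteTimeSeries(times, signals)


def write_timeseries(ts: MetaboliteTimeSeries, path) -> None:
    ts.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parameter JSON


def write_parameters(
    path,
    kinetic: KineticParameters | None = None,
    acquisition: AcquisitionParameters | None = None,
) -> None:
    doc = {}
    if kinetic is not None:
        doc["kinetic"] = dataclasses.asdict(kinetic)
    if acquisition is not None:
        doc["acquisition"] = dataclasses.asdict(acquisition)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_parameters(path):
    """Load ``(KineticParameters | None, AcquisitionParameters | None)``."""
    doc = json.loads(Path(path).read_text())
    kinetic = acquisition = None
    if "kinetic" in doc:
        try:
            kinetic = KineticParameters(**doc["kinetic"])
        except TypeError as exc:
            raise ValidationError(f"{path}: bad kinetic block: {exc}") from exc
    if "acquisition" in doc:
        try:
            acquisition = AcquisitionParameters(**doc["acquisition"])
        except TypeError as exc:
            raise ValidationError(f"{path}: bad acquisition block: {exc}") from exc
    return kinetic, acquisition


# ---------------------------------------------------------------------------
# spectra


def write_spectra(st: SpectraStack, matrix_path, meta_path=None) -> None:
    """Matrix CSV (first row = ppm axis, one row per spectrum) + metadata."""
    matrix_path = Path(matrix_path)
    arr = np.vstack([st.ppm_axis, st.spectra])
    np.savetxt(matrix_path, arr, delimiter=",")
    meta = {
        "times_s": st.times_s.tolist(),
        "peak_registry": {
            lab: dataclasses.asdict(pk) for lab, pk in st.peak_registry.items()
        },
        "warnings": list(st.warnings),
    }
    meta_path = Path(meta_path) if meta_path else matrix_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_spectra(matrix_path, meta_path=None) -> SpectraStack:
    matrix_path = Path(matrix_path)
    arr = np.loadtxt(matrix_path, delimiter=",")
    meta_path = Path(meta_path) if meta_path else matrix_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    registry = {lab: PeakShape(**pk) for lab, pk in meta["peak_registry"].items()}
    return SpectraStack(
        ppm_axis=arr[0],
        times_s=np.asarray(meta["times_s"], dtype=float),
        spectra=arr[1:],
        peak_registry=registry,
        warnings=list(meta.get("warnings", [])),
    )


# ---------------------------------------------------------------------------
# reports


def _jsonify(obj, path="$"):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v, f"{path}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v, f"{path}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj), path)
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise ValidationError(f"unserializable report field at {path}: {type(obj).__name__}")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_report(
    command: str,
    config: dict,
    results: dict,
    seed: int | None = None,
    input_paths: tuple = (),
) -> dict:
    """Assemble a versioned, machine-readable run report."""
    return {
        "command": command,
        "package": "hyperkin",
        "version": __version__,
        "seed": seed,
        "config": _jsonify(config, "$.config"),
        "inputs": {str(p): _hash_file(p) for p in input_paths},
        "results": _jsonify(results, "$.results"),
    }


def write_report(report: dict, path=None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
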