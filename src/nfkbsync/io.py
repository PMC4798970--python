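"""Validated readers/writers for trace and expression files, plus run manifests.

Traces travel as long (tidy) CSV — ``cell_id,time_min,nci`` — because
tracks have unequal lengths; expression matrices as wide TSV with a
``gene_id`` column and one ``time_<min>`` column per sample, matching
each datatype's natural shape.  Readers re-validate the container
invariants (uniform sampling, positivity, t=0 reference) and fail with
the offending location rather than propagating bad data.
"""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_patterns import ExpressionMatrix
from .trace_analysis import TraceSet

__all__ = [
    "read_traces", "write_traces", "read_expression", "write_expression",
    "write_manifest",
]


def write_traces(traces: TraceSet, path) -> None:
    df = traces.to_frame()
    df.to_csv(path, index=False)


def read_traces(path, sampling_interval: float | None = None) -> TraceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cell_id", "time_min", "nci"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    bad = df.index[~np.isfinite(df["nci"]) | (df["nci"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: invalid NCI value at data row {bad[0] + 2}")
    try:
        return TraceSet.from_frame(df, sampling_interval=sampling_interval)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path, detection_path=None) -> None:
    out = matrix.values.copy()
    out.columns = [f"time_{t:g}" for t in matrix.timepoints_min]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if detection_path is not None and matrix.detection_p is not None:
        p = matrix.detection_p.copy()
        p.columns = out.columns
        p.index.name = "gene_id"
        p.to_csv(detection_path, sep="\t")


def read_expression(path, detection_path=None,
                    require_t0: bool = True) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    times = []
    for col in df.columns:
        name = str(col)
        if not name.startswith("time_"):
            raise ValueError(f"{path}: unexpected column {name!r} (want time_<min>)")
        times.append(float(name[5:]))
    times = np.asarray(times)
    if require_t0 and (len(times) == 0 or times[0] != 0):
        raise ValueError(f"{path}: first column must be time_0 (the reference timepoint)")
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col="gene_id",
                                float_precision="round_trip")
        detection.columns = df.columns
        detection = detection.loc[df.index]
    return ExpressionMatrix(df, times, detection_p=detection)


def write_manifest(out_path, command: str, seeds: dict, inputs: dict,
                   outputs: dict, config: dict | None = None) -> Path:
    """Write the per-run provenance manifest next to ``out_path``."""
    from importlib.metadata import version, PackageNotFoundError
    try:
        pkg_version = version("nfkbsync")
    except PackageNotFoundError:
        pkg_version = "unknown"
    config_blob = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "package_version": pkg_version,
        "python": sys.version.split()[0],
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "config": config or {},
    }
    out_path = Path(out_path)
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
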