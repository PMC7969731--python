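"""Plain-text serialization: TSV matrices, JSON models and reports.

Run matrices are stored as TSV with one header row of voxel ids; sample
matrices carry a JSON sidecar with labels, run ids and provenance; the
fitted decoder round-trips through JSON.  All writers produce text files
only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import ARDLogisticModel
from .preprocess import SampleMatrix, VolumeSeries

__all__ = [
    "write_volume_series",
    "read_volume_series",
    "write_samples",
    "read_samples",
    "write_model",
    "read_model",
]


def write_volume_series(series: VolumeSeries, path) -> None:
    path = Path(path)
    df = pd.DataFrame(series.data, columns=[str(v) for v in series.voxel_ids])
    with path.open("w") as fh:
        fh.write(
            f"# tr_seconds={series.tr_seconds}\trun_id={series.run_id}\t"
            f"scan_role={series.scan_role}\thistory={','.join(series.history)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_volume_series(path) -> VolumeSeries:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().lstrip("#").strip()
        meta = dict(item.split("=", 1) for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t")
    history = tuple(h for h in meta.get("history", "").split(",") if h)
    return VolumeSeries(
        data=df.to_numpy(dtype=float),
        tr_seconds=float(meta["tr_seconds"]),
        run_id=int(meta["run_id"]),
        scan_role=meta["scan_role"],
        voxel_ids=np.array([int(c) for c in df.columns]),
        history=history,
    )


def write_samples(samples: SampleMatrix, path) -> None:
    """TSV matrix plus a .json sidecar with labels/run ids/provenance."""
    path = Path(path)
    pd.DataFrame(
        samples.data, columns=[str(v) for v in samples.voxel_ids]
    ).to_csv(path, sep="\t", index=False)
    sidecar = {
        "labels": None if samples.labels is None else [str(x) for x in samples.labels],
        "run_ids": [int(r) for r in samples.run_ids],
        "provenance": [list(p) for p in samples.provenance],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_samples(path) -> SampleMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SampleMatrix(
        data=df.to_numpy(dtype=float),
        labels=None if meta["labels"] is None else np.array(meta["labels"]),
        run_ids=np.array(meta["run_ids"]),
        voxel_ids=np.array([int(c) for c in df.columns]),
        provenance=tuple(tuple(p) for p in meta["provenance"]),
    )


def write_model(model: ARDLogisticModel, path) -> None:
    payload = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "relevance": [
            None if not np.isfinite(a) else float(a) for a in model.relevance
        ],
        "retained_index": model.retained_index.tolist(),
        "voxel_ids": model.voxel_ids.tolist(),
        "class_labels": [str(c) for c in model.class_labels],
        "n_iterations": model.n_iterations,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> ARDLogisticModel:
    meta = json.loads(Path(path).read_text())
    relevance = np.array(
        [np.inf if a is None else a for a in meta["relevance"]], dtype=float
    )
    return ARDLogisticModel(
        weights=np.array(meta["weights"], dtype=float),
        bias=float(meta["bias"]),
        relevance=relevance,
        retained_index=np.array(meta["retained_index"], dtype=int),
        voxel_ids=np.array(meta["voxel_ids"]),
        class_labels=tuple(meta["class_labels"]),
        n_iterations=int(meta["n_iterations"]),
        converged=bool(meta["converged"]),
    )
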