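"""Dataset readers/writers and result serialization.

The text time-series format is a delimited matrix with a header row of node
labels and one row per time point; sampling rate and provenance travel in a
JSON sidecar (``<file>.json``) when available.  Benchmark-style containers
(MAT files holding a stacked ``ts`` array and per-run ``net`` ground-truth
adjacencies) are mapped to a list of datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .train import SignMaps

__all__ = ["Dataset", "read_dataset", "write_dataset", "write_results"]


@dataclass
class Dataset:
    """Time x nodes matrix with metadata and optional ground truth."""

    ts: np.ndarray
    fs: float = 1.0
    truth: np.ndarray | None = None  # directed adjacency, truth[i, j]: i -> j
    node_labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        if self.ts.ndim != 2:
            raise ValueError("ts must be 2-D (time x nodes)")
        if not self.node_labels:
            self.node_labels = [f"node{i}" for i in range(self.ts.shape[1])]
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != (self.ts.shape[1], self.ts.shape[1]):
                raise ValueError("truth adjacency must be n_nodes x n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.ts.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.ts.shape[0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_dataset(path, fmt: str | None = None, fs: float | None = None):
    """Read a dataset; returns a Dataset, or a list for benchmark containers.

    ``fmt`` is one of {"csv", "tsv", "benchmark-mat"}; by default it is
    inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mat": "benchmark-mat"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if fmt == "benchmark-mat":
        return _read_benchmark_mat(path)

    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Dataset(
        ts=frame.to_numpy(dtype=float),
        fs=float(fs if fs is not None else meta.get("fs", 1.0)),
        node_labels=[str(c) for c in frame.columns],
        metadata=meta,
    )


def _read_benchmark_mat(path: Path) -> list[Dataset]:
    from scipy.io import loadmat

    raw = loadmat(path)
    missing = [k for k in ("ts", "net") if k not in raw]
    if missing:
        raise ValueError(f"benchmark container {path} lacks field(s): {missing}")
    ts = np.asarray(raw["ts"], dtype=float)
    net = np.asarray(raw["net"], dtype=float)
    if net.ndim == 2:
        net = net[None]
    n_subjects = int(raw["Nsubjects"].squeeze()) if "Nsubjects" in raw else net.shape[0]
    if "Ntimepoints" in raw:
        n_time = int(raw["Ntimepoints"].squeeze())
    else:
        if ts.shape[0] % n_subjects:
            raise ValueError("cannot split ts rows evenly across subjects")
        n_time = ts.shape[0] // n_subjects
    if ts.shape[0] != n_subjects * n_time:
        raise ValueError(
            f"ts has {ts.shape[0]} rows, expected {n_subjects} x {n_time}"
        )
    datasets = []
    for s in range(n_subjects):
        block = ts[s * n_time : (s + 1) * n_time]
        truth = net[s] if net.shape[0] == n_subjects else net[0]
        datasets.append(
            Dataset(
                ts=block,
                truth=(np.abs(truth) > 0).astype(float),
                metadata={"subject": s, "source": str(path)},
            )
        )
    return datasets


def write_dataset(dataset: Dataset, path, fmt: str = "tsv") -> None:
    """Write matrix + JSON metadata sidecar."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    frame = pd.DataFrame(dataset.ts, columns=dataset.node_labels)
    frame.to_csv(path, sep=sep, index=False)
    meta = dict(dataset.metadata)
    meta.update({"fs": dataset.fs, "version": __version__})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_results(results, path, kind: str) -> None:
    """Serialize results deterministically.

    kind="edges": iterable of dicts -> CSV; kind="grid": GridResult -> CSV;
    kind="maps": SignMaps -> JSON.  A version string is embedded in every
    output.
    """
    path = Path(path)
    if kind == "edges":
        columns = ["source", "target", "method", "statistic", "verdict"]
        rows = list(results)
        frame = pd.DataFrame(rows, columns=columns if not rows else None)
        if rows:
            ordered = [c for c in columns if c in frame.columns] + [
                c for c in frame.columns if c not in columns
            ]
            frame = frame[ordered]
        frame.insert(0, "version", __version__)
        frame.to_csv(path, index=False)
    elif kind == "grid":
        frame = results.to_frame()
        frame.insert(0, "version", __version__)
        frame.to_csv(path, index=False)
    elif kind == "maps":
        if not isinstance(results, SignMaps):
            raise TypeError("kind='maps' expects a SignMaps instance")
        results.save(path)
    else:
        raise ValueError(f"unknown result kind {kind!r}")
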