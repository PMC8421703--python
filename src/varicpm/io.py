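"""Node time series, atlas handling and on-disk formats.

Node signals live in :class:`NodeTimeSeries` (nodes × samples, row *k* is
node *k+1*).  They are read either directly from tab-separated node×time
tables or extracted from preprocessed 4D NIfTI volumes against a sphere
atlas (:func:`extract_node_timeseries`).  A scan manifest (TSV with columns
participant_id, scan_id, condition, path) keys a cohort's scans.

Conventions fixed here and used throughout the package:

* sample indexing is 0-based, half-open;
* atlas node ids are 1-based and contiguous;
* world coordinates are MNI millimetres; a voxel belongs to a sphere when
  its *center* lies within ``diameter / 2`` of the node center (Euclidean
  distance in mm).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "NodeTimeSeries",
    "Atlas",
    "NETWORKS_14",
    "synthetic_atlas",
    "extract_node_timeseries",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "load_manifest",
]

PROVENANCES = ("gsr", "no_gsr", "synthetic")

#: The 14 functional networks of the 264-sphere parcellation, with the
#: node counts of the published partition (used by :func:`synthetic_atlas`).
NETWORKS_14: dict[str, int] = {
    "visual": 31,
    "sensory_somatomotor_hand": 30,
    "sensory_somatomotor_mouth": 5,
    "cingulo_opercular": 14,
    "auditory": 13,
    "default_mode": 58,
    "memory_retrieval": 5,
    "ventral_attention": 9,
    "salience": 18,
    "subcortical": 13,
    "frontoparietal": 25,
    "dorsal_attention": 11,
    "cerebellar": 4,
    "uncertain": 28,
}


@dataclass
class NodeTimeSeries:
    """One participant-scan's node×time signal matrix.

    ``condition`` is ``"rest"`` or a task-condition label; ``provenance``
    records the nuisance-removal strategy of the upstream preprocessing
    (``gsr`` / ``no_gsr``) or ``synthetic`` for simulated data.
    """

    participant_id: str
    scan_id: str
    condition: str
    data: np.ndarray
    tr_seconds: float
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a nodes×samples matrix")
        if self.data.shape[1] < 2:
            raise ValueError("at least 2 samples are required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def drop_initial(self, n: int) -> "NodeTimeSeries":
        """Copy with the first ``n`` samples removed (scanner equilibration)."""
        if not 0 <= n < self.n_samples - 1:
            raise ValueError(f"cannot drop {n} of {self.n_samples} samples")
        return NodeTimeSeries(
            self.participant_id,
            self.scan_id,
            self.condition,
            self.data[:, n:].copy(),
            self.tr_seconds,
            self.provenance,
        )


@dataclass
class Atlas:
    """Sphere parcellation: node centers in MNI mm, diameters, networks.

    ``table`` columns: node_id (1..N contiguous), x, y, z, diameter_mm,
    network.
    """

    table: pd.DataFrame

    REQUIRED = ("node_id", "x", "y", "z", "diameter_mm", "network")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table lacks column(s) {missing}")
        ids = self.table["node_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("node_ids must be unique and contiguous from 1")
        if (self.table["diameter_mm"] <= 0).any():
            raise ValueError("diameters must be positive")
        if self.table["network"].isna().any():
            raise ValueError("every node needs a network label")
        self.table = self.table.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def network_of(self, node_id: int) -> str:
        if not 1 <= node_id <= self.n_nodes:
            raise KeyError(f"unknown node_id {node_id}")
        return str(self.table.loc[node_id - 1, "network"])

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "Atlas":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def synthetic_atlas(n_nodes: int = 264, seed: int = 0, diameter_mm: float = 10.0) -> Atlas:
    """Synthetic stand-in for the 264-sphere parcellation.

    The published atlas coordinates are not redistributable here, so tests
    and simulations use random non-overlapping sphere centers on a jittered
    lattice inside a brain-sized bounding box, with network labels drawn in
    the published 14-network proportions.  Geometry is synthetic; the
    network partition sizes are faithful at ``n_nodes=264``.
    """
    rng = np.random.default_rng(seed)
    spacing = diameter_mm + 2.0
    axes = [np.arange(-66, 67, spacing), np.arange(-96, 67, spacing), np.arange(-42, 73, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(grid) < n_nodes:
        raise ValueError(f"bounding box holds only {len(grid)} spheres")
    centers = grid[rng.choice(len(grid), size=n_nodes, replace=False)]
    centers = centers + rng.uniform(-0.5, 0.5, size=centers.shape)
    total = sum(NETWORKS_14.values())
    counts = {k: max(1, int(round(v * n_nodes / total))) for k, v in NETWORKS_14.items()}
    labels: list[str] = []
    for k, c in counts.items():
        labels.extend([k] * c)
    # trim / pad to exactly n_nodes using the largest network
    labels = labels[:n_nodes]
    while len(labels) < n_nodes:
        labels.append("default_mode")
    rng.shuffle(labels)
    table = pd.DataFrame(
        {
            "node_id": np.arange(1, n_nodes + 1),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "diameter_mm": diameter_mm,
            "network": labels,
        }
    )
    return Atlas(table)


def extract_node_timeseries(
    volume: "nib.Nifti1Image | str | os.PathLike",
    atlas: Atlas,
    *,
    participant_id: str = "unknown",
    scan_id: str = "scan",
    condition: str = "rest",
    tr_seconds: float | None = None,
    provenance: str = "no_gsr",
) -> NodeTimeSeries:
    """Mean sphere-ROI signal per node from a preprocessed 4D volume.

    A voxel contributes to a node when its center lies within
    ``diameter/2`` of the node's MNI center.  Nodes whose sphere contains
    no voxel are a hard error listing every offending node.
    """
    img = nib.load(str(volume)) if not isinstance(volume, nib.spatialimages.SpatialImage) else volume
    if img.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {img.ndim}D")
    affine = img.affine
    if affine is None:
        raise ValueError("volume has no affine; cannot map voxels to MNI mm")
    data = np.asanyarray(img.dataobj, dtype=float)
    nx, ny, nz, nt = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = (vox @ affine.T)[:, :3]
    flat = data.reshape(-1, nt)
    out = np.empty((atlas.n_nodes, nt))
    empty: list[int] = []
    centers = atlas.coordinates
    radii = atlas.table["diameter_mm"].to_numpy(dtype=float) / 2.0
    for row in range(atlas.n_nodes):
        d2 = np.sum((world - centers[row]) ** 2, axis=1)
        mask = d2 <= radii[row] ** 2
        if not mask.any():
            empty.append(int(atlas.table.loc[row, "node_id"]))
            continue
        out[row] = flat[mask].mean(axis=0)
    if empty:
        raise ValueError(f"sphere(s) with zero voxels for node_id(s) {empty}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return NodeTimeSeries(participant_id, scan_id, condition, out, tr_seconds, provenance)


# ---------------------------------------------------------------------------
# plain-text round trip


def write_timeseries_tsv(ts: NodeTimeSeries, path: str | os.PathLike) -> None:
    """Nodes-as-rows TSV with a header row of sample times (seconds)."""
    times = np.arange(ts.n_samples) * ts.tr_seconds
    df = pd.DataFrame(ts.data, columns=[f"{t:.10g}" for t in times])
    df.insert(0, "node_id", np.arange(1, ts.n_nodes + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.17e")


def read_timeseries_tsv(
    path: str | os.PathLike,
    *,
    participant_id: str,
    scan_id: str,
    condition: str,
    provenance: str = "synthetic",
) -> NodeTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    times = np.asarray([float(c) for c in df.columns[1:]])
    if len(times) < 2:
        raise ValueError(f"{path}: needs at least 2 sample columns")
    tr = float(times[1] - times[0])
    return NodeTimeSeries(
        participant_id, scan_id, condition, df.iloc[:, 1:].to_numpy(float), tr, provenance
    )


def load_manifest(
    path: str | os.PathLike,
    *,
    atlas: Atlas | None = None,
    conditions: Sequence[str] | None = None,
    provenance: str = "synthetic",
) -> dict[tuple[str, str, str], NodeTimeSeries]:
    """Load every scan referenced by a manifest TSV.

    Returns a dict keyed by (participant_id, scan_id, condition).  Errors:
    a missing file (named), a duplicate key, a node-count mismatch across
    scans, or a condition outside the configured set.
    """
    root = Path(path).parent
    man = pd.read_csv(path, sep="\t", dtype=str)
    need = {"participant_id", "scan_id", "condition", "path"}
    if not need <= set(man.columns):
        raise ValueError(f"manifest lacks column(s) {sorted(need - set(man.columns))}")
    out: dict[tuple[str, str, str], NodeTimeSeries] = {}
    n_nodes: int | None = None
    for _, row in man.iterrows():
        key = (row["participant_id"], row["scan_id"], row["condition"])
        if key in out:
            raise ValueError(f"duplicate manifest entry {key}")
        if conditions is not None and row["condition"] not in ("rest", *conditions):
            raise ValueError(f"unknown condition {row['condition']!r} in manifest")
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = root / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file {fpath}")
        ts = read_timeseries_tsv(
            fpath,
            participant_id=key[0],
            scan_id=key[1],
            condition=key[2],
            provenance=provenance,
        )
        if n_nodes is None:
            n_nodes = ts.n_nodes
        elif ts.n_nodes != n_nodes:
            raise ValueError(
                f"node-count mismatch: {fpath} has {ts.n_nodes} nodes, expected {n_nodes}"
            )
        if atlas is not None and ts.n_nodes != atlas.n_nodes:
            raise ValueError(
                f"{fpath}: {ts.n_nodes} nodes does not match atlas ({atlas.n_nodes})"
            )
        out[key] = ts
    return out
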