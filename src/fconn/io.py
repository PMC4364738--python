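"""Readers and writers for every plain-text artifact of the pipeline.

Time series, motion tables and manifests travel as TSV; networks as
edge-list TSV (10 significant digits, lossless for round-tripping through
text); partitions as TSV; results as JSON.  BrainNet-viewer .node/.edge
exports are provided for surface rendering by external tools.  Writers can
stamp a provenance header (``# key=value`` comment lines) that readers
skip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import WeightedNetwork

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
    "read_edge_list",
    "write_edge_list",
    "write_partition",
    "read_partition",
    "write_brainnet_files",
    "write_json",
    "read_json",
]

_W_FMT = "%.10g"


def _write_header(fh, provenance: dict | None) -> None:
    if provenance:
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")


def write_timeseries(path, ts: np.ndarray, roi_ids=None, provenance=None) -> None:
    """Rows = volumes, columns = ROI ids ('roi_0001'...)."""
    ts = np.asarray(ts, dtype=float)
    if roi_ids is None:
        roi_ids = [f"roi_{k + 1:04d}" for k in range(ts.shape[1])]
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("\t".join(roi_ids) + "\n")
        np.savetxt(fh, ts, delimiter="\t", fmt=_W_FMT)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV time-series table; returns (matrix, roi ids)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        raise ValueError(f"non-numeric cells in column(s): {list(bad)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"ragged or missing values around row {row}")
    return df.to_numpy(dtype=float), list(df.columns)


_MOTION_COLS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def write_motion(path, motion: np.ndarray, provenance=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("\t".join(_MOTION_COLS) + "\n")
        np.savetxt(fh, np.asarray(motion, dtype=float), delimiter="\t", fmt=_W_FMT)


def read_motion(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    return df.to_numpy(dtype=float)


def write_manifest(path, manifest: pd.DataFrame, provenance=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        manifest.to_csv(fh, sep="\t")


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_edge_list(path, net: WeightedNetwork, provenance=None) -> None:
    """Edge-list TSV: node_i, node_j, weight (0-based ids)."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write(f"# n_nodes={net.n_nodes}\n")
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in zip(net.i, net.j, net.w):
            fh.write(f"{i}\t{j}\t{w:.10g}\n")


def read_edge_list(path) -> WeightedNetwork:
    n_nodes = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# n_nodes="):
                n_nodes = int(line.strip().split("=", 1)[1])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if n_nodes is None:
        n_nodes = int(df[["node_i", "node_j"]].to_numpy().max()) + 1 if len(df) else 0
    return WeightedNetwork(
        n_nodes,
        df["node_i"].to_numpy(dtype=np.intp),
        df["node_j"].to_numpy(dtype=np.intp),
        df["weight"].to_numpy(dtype=float),
    )


def write_partition(path, labels: np.ndarray, provenance=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("node_id\tmodule_id\n")
        for k, lab in enumerate(np.asarray(labels)):
            fh.write(f"{k}\t{int(lab)}\n")


def read_partition(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.sort_values("node_id")["module_id"].to_numpy(dtype=np.intp)


def _unit_sphere_coords(n: int) -> np.ndarray:
    """Deterministic Fibonacci-sphere layout for synthetic node coordinates."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) * 80.0


def write_brainnet_files(
    out_prefix,
    net: WeightedNetwork,
    nodal_size: np.ndarray,
    module_labels: np.ndarray,
    flagged=None,
    coords: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write BrainNet-viewer .node and .edge files (1-based display ids).

    The .node color column carries the module id (flagged nodes offset by
    the module count to render distinctly); size carries nodal efficiency.
    """
    out_prefix = Path(out_prefix)
    n = net.n_nodes
    if coords is None:
        coords = _unit_sphere_coords(n)
    flagged_mask = np.zeros(n, dtype=bool)
    if flagged is not None:
        flagged_mask[np.asarray(flagged, dtype=int)] = True
    n_mod = int(np.asarray(module_labels).max()) + 1
    node_path = out_prefix.with_suffix(".node")
    with open(node_path, "w") as fh:
        for k in range(n):
            color = int(module_labels[k]) + (n_mod if flagged_mask[k] else 0) + 1
            fh.write(
                f"{coords[k, 0]:.4f}\t{coords[k, 1]:.4f}\t{coords[k, 2]:.4f}"
                f"\t{color}\t{nodal_size[k]:.6g}\tnode_{k + 1:04d}\n"
            )
    edge_path = out_prefix.with_suffix(".edge")
    np.savetxt(edge_path, net.to_matrix(), delimiter="\t", fmt="%.6g")
    return node_path, edge_path


class _NumpyJSON(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyJSON)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
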