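"""Connectome construction and edge vectorization.

Connectomes are raw (unstandardized) Pearson correlation matrices over the
parcellation's ROIs. The edge universe is the strict upper triangle in
row-major order, i.e. edge (a, b) with a < b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import ParcellationScheme

SYMMETRY_TOL = 1e-8


def edge_index(n_rois: int) -> np.ndarray:
    """(E, 2) array of ROI pairs (a, b), a < b, row-major upper triangle."""
    rows, cols = np.triu_indices(n_rois, k=1)
    return np.column_stack([rows, cols])


def edge_names(scheme: ParcellationScheme) -> list[str]:
    names = scheme.roi_names
    return [f"{names[a]}__{names[b]}" for a, b in edge_index(scheme.n_rois)]


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric unit-diagonal Pearson correlation matrix for one time point."""

    values: np.ndarray
    parcellation: ParcellationScheme
    time_point: str  # "TP1" | "TP2"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if v.shape[0] != self.parcellation.n_rois:
            raise ValueError(
                f"matrix size {v.shape[0]} != parcellation size "
                f"{self.parcellation.n_rois}"
            )
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise ValueError("connectome matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("connectome diagonal must be 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def edges(self) -> "EdgeVector":
        return vectorize_edges(self.values)


@dataclass(frozen=True)
class EdgeVector:
    """Strict-upper-triangle vectorization of a symmetric ROI x ROI matrix."""

    values: np.ndarray
    index: np.ndarray  # (E, 2) pairs, a < b

    def __post_init__(self) -> None:
        if len(self.values) != len(self.index):
            raise ValueError("values and index length mismatch")

    @property
    def n_edges(self) -> int:
        return len(self.values)


def build_connectome(
    ts: np.ndarray,
    scheme: ParcellationScheme,
    time_point: str = "TP1",
) -> ConnectomeMatrix:
    """Pairwise Pearson correlation connectome from a T x P time-series matrix.

    Columns of `ts` must be ordered as the parcellation ROIs. Connectomes are
    kept as raw r; see :func:`fisher_z` for the optional variance-stabilized
    view used in sensitivity checks.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D T x P array")
    if ts.shape[1] != scheme.n_rois:
        raise ValueError(
            f"time series has {ts.shape[1]} columns, parcellation has "
            f"{scheme.n_rois} ROIs"
        )
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [scheme.roi_names[i] for i in flat]
        raise ValueError(f"constant time series for ROI(s): {names}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return ConnectomeMatrix(r, scheme, time_point)


def fisher_z(matrix: np.ndarray) -> np.ndarray:
    """arctanh of off-diagonal correlations (diagonal set to 0).

    Off by default throughout the pipeline; provided for sensitivity checks.
    """
    m = np.asarray(matrix, dtype=float)
    z = np.arctanh(np.clip(m, -1 + 1e-15, 1 - 1e-15))
    np.fill_diagonal(z, 0.0)
    return z


def delta_connectome(c1: ConnectomeMatrix, c2: ConnectomeMatrix) -> np.ndarray:
    """Elementwise TP2 - TP1 difference matrix (symmetric, zero diagonal)."""
    if c1.parcellation is not c2.parcellation and not c1.parcellation.table.equals(
        c2.parcellation.table
    ):
        raise ValueError("connectomes use different parcellations")
    if c1.values.shape != c2.values.shape:
        raise ValueError("connectome shape mismatch")
    return c2.values - c1.values


def vectorize_edges(matrix: np.ndarray, tol: float = SYMMETRY_TOL) -> EdgeVector:
    """Vectorize a symmetric P x P matrix into its strict upper triangle."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError(f"matrix asymmetry exceeds tolerance {tol}")
    m = (m + m.T) / 2.0
    idx = edge_index(m.shape[0])
    return EdgeVector(m[idx[:, 0], idx[:, 1]], idx)


def devectorize_edges(
    edges: EdgeVector | np.ndarray, n_rois: int, diagonal: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (diagonal filled with `diagonal`)."""
    values = edges.values if isinstance(edges, EdgeVector) else np.asarray(edges)
    expected = n_rois * (n_rois - 1) // 2
    if len(values) != expected:
        raise ValueError(f"expected {expected} edges for P={n_rois}, got {len(values)}")
    m = np.full((n_rois, n_rois), diagonal, dtype=float)
    rows, cols = np.triu_indices(n_rois, k=1)
    m[rows, cols] = values
    m[cols, rows] = values
    return m
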