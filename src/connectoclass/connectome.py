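"""Per-subject functional connectivity: Pearson correlation matrices and
their vectorized (strict lower triangle) feature form.

The connectivity matrix of a subject is the region-by-region Pearson
correlation of the regional mean time series.  Features for classification
are the strict lower triangle flattened row-major (i > j), i.e. the order
(1,0), (2,0), (2,1), (3,0), ... — ``n(n-1)/2`` values (4005 for 90
regions).  The index map returned alongside makes the feature order
auditable and lets importance maps be folded back onto region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "compute_fc",
    "vectorize_fc",
    "devectorize_fc",
    "fisher_z",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric (atol 1e-12)")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("connectivity matrix diagonal must be exactly 1")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match matrix size")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def default_labels(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def compute_fc(
    timeseries: np.ndarray, region_labels: list[str] | None = None
) -> ConnectivityMatrix:
    """Pearson correlations between all pairs of regional time courses.

    ``timeseries`` is (n_timepoints, n_regions) with time along rows.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D (time x regions) matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points to correlate")
    if not np.all(np.isfinite(ts)):
        raise ValueError("timeseries contains non-finite values")
    labels = region_labels or default_labels(ts.shape[1])
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time course for region(s): {', '.join(bad)}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, region_labels=labels)


def lower_triangle_index_map(n: int) -> list[tuple[int, int]]:
    """Feature position -> (i, j) region pair, row-major strict lower triangle."""
    rows, cols = np.tril_indices(n, k=-1)
    return list(zip(rows.tolist(), cols.tolist()))


def vectorize_fc(
    matrix: ConnectivityMatrix,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flatten the strict lower triangle into the fixed feature order.

    Returns ``(vector, index_map)`` where ``index_map[k]`` is the region
    pair (i, j), i > j, stored at feature position k.
    """
    n = matrix.n_regions
    rows, cols = np.tril_indices(n, k=-1)
    return matrix.values[rows, cols].copy(), list(zip(rows.tolist(), cols.tolist()))


def devectorize_fc(
    vector: np.ndarray, region_labels: list[str] | None = None
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_fc` (unit diagonal restored)."""
    vector = np.asarray(vector, dtype=float)
    p = vector.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if n * (n - 1) // 2 != p:
        raise ValueError(f"vector length {p} is not n(n-1)/2 for any integer n")
    m = np.eye(n)
    rows, cols = np.tril_indices(n, k=-1)
    m[rows, cols] = vector
    m[cols, rows] = vector
    return ConnectivityMatrix(values=m, region_labels=region_labels or default_labels(n))


def fisher_z(matrix: ConnectivityMatrix, eps: float = 1e-7) -> ConnectivityMatrix:
    """Optional Fisher r-to-z variance-stabilizing transform (off by default
    in the pipeline, which feeds raw correlations to the classifiers)."""
    v = np.clip(matrix.values, -1.0 + eps, 1.0 - eps)
    z = np.arctanh(v)
    np.fill_diagonal(z, 1.0)
    # z-values exceed 1 in magnitude; wrap without the unit-range check
    out = ConnectivityMatrix.__new__(ConnectivityMatrix)
    out.values = (z + z.T) / 2.0
    np.fill_diagonal(out.values, 1.0)
    out.region_labels = list(matrix.region_labels)
    return out
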