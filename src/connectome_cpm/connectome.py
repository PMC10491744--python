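"""Connectivity matrices: construction, edge vectorization, QC.

A subject's connectome is a symmetric node-by-node matrix of Fisher
z-transformed Pearson correlations between node time courses.  The diagonal
is undefined (stored as NaN) and never enters any statistic.  Edges are
flattened to a canonical vector over the upper triangle (i < j, row-major),
the ordering used by every downstream module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: |r| is clamped to this bound before atanh so edge weights stay finite.
R_CLAMP = 1.0 - 1e-7

_SYMMETRY_TOL = 1e-10


class ConnectomeError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric Fisher-z connectivity matrix.

    ``values`` is ``n_nodes x n_nodes`` with NaN on the diagonal.  Edges
    incident to nodes listed in ``undefined_nodes`` (e.g. nodes with a
    zero-variance time course) are NaN as well and are reported, never
    silently zeroed.  All other off-diagonal entries must be finite and
    symmetric to 1e-10.
    """

    subject_id: str
    values: np.ndarray
    undefined_nodes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectomeError(f"connectivity matrix must be square, got {v.shape}")
        asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ConnectomeError(
                f"matrix for {self.subject_id!r} asymmetric (max |A - A.T| = {asym:.3g})"
            )
        v = (v + v.T) / 2.0  # exact symmetry after tolerance check
        np.fill_diagonal(v, np.nan)
        mask = np.zeros(v.shape, dtype=bool)
        for i in self.undefined_nodes:
            mask[i, :] = mask[:, i] = True
        np.fill_diagonal(mask, True)
        if not np.all(np.isfinite(v[~mask])):
            raise ConnectomeError(
                f"non-finite off-diagonal edge weights for {self.subject_id!r} "
                "outside the declared undefined nodes"
            )
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def n_edges_for(n_nodes: int) -> int:
    """Number of off-diagonal undirected edges: n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def n_nodes_for(n_edges: int) -> int:
    """Invert n(n-1)/2; raise if no integer solution."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_edges_for(n) != n_edges:
        raise ConnectomeError(f"{n_edges} is not n*(n-1)/2 for any integer n")
    return n


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: upper triangle, i < j, row-major."""
    return np.triu_indices(n_nodes, k=1)


def edge_names(n_nodes: int) -> list[str]:
    """1-based ``i_j`` names for the canonical edge ordering."""
    ii, jj = edge_pairs(n_nodes)
    return [f"{i + 1}_{j + 1}" for i, j in zip(ii, jj)]


def compute_connectivity(
    node_timeseries: np.ndarray, subject_id: str
) -> ConnectivityMatrix:
    """Build a Fisher-z connectivity matrix from node time courses.

    Each off-diagonal entry (i, j) is atanh(clamp(r_ij)) where r_ij is the
    Pearson correlation of rows i and j and |r| is clamped to ``R_CLAMP``
    before the transform.  Nodes with zero-variance time courses get NaN
    edges and are recorded in ``undefined_nodes``.
    """
    ts = np.asarray(node_timeseries, dtype=np.float64)
    if ts.ndim != 2:
        raise ConnectomeError("node_timeseries must be 2-D (nodes x timepoints)")
    n_nodes, n_t = ts.shape
    if n_t < 3:
        raise ConnectomeError(f"need >= 3 timepoints, got {n_t}")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    values = np.full((n_nodes, n_nodes), np.nan)
    good = np.flatnonzero(sd > 0.0)
    if good.size >= 2:
        r = np.corrcoef(ts[good])
        r = np.clip(r, -R_CLAMP, R_CLAMP)
        # mirror the upper triangle so symmetry is exact
        r = np.triu(r, k=1)
        z = np.arctanh(r + r.T)
        values[np.ix_(good, good)] = z
    if bad.size:
        warnings.warn(
            f"subject {subject_id!r}: zero-variance time course for node(s) "
            f"{[int(b) for b in bad]}; their edges are undefined",
            stacklevel=2,
        )
    return ConnectivityMatrix(subject_id, values, undefined_nodes=tuple(int(b) for b in bad))


def vectorize(matrix: ConnectivityMatrix) -> np.ndarray:
    """Flatten the off-diagonal entries to the canonical edge vector."""
    ii, jj = edge_pairs(matrix.n_nodes)
    return matrix.values[ii, jj].copy()


def devectorize(
    vector: np.ndarray, n_nodes: int | None = None, subject_id: str = ""
) -> ConnectivityMatrix:
    """Rebuild a ConnectivityMatrix from a canonical edge vector."""
    vector = np.asarray(vector, dtype=np.float64)
    if n_nodes is None:
        n_nodes = n_nodes_for(vector.size)
    elif vector.size != n_edges_for(n_nodes):
        raise ConnectomeError(
            f"edge vector of length {vector.size} inconsistent with n_nodes={n_nodes}"
        )
    values = np.full((n_nodes, n_nodes), np.nan)
    ii, jj = edge_pairs(n_nodes)
    values[ii, jj] = vector
    values[jj, ii] = vector
    bad = tuple(
        int(i) for i in range(n_nodes)
        if np.all(np.isnan(np.delete(values[i], i)))
    ) if np.any(np.isnan(vector)) else ()
    return ConnectivityMatrix(subject_id, values, undefined_nodes=bad)


def outlier_scores(edge_matrix: np.ndarray) -> np.ndarray:
    """Similarity of each subject to the median connectome of the others.

    Returns, per subject, the Pearson correlation between that subject's
    edge vector and the elementwise median edge vector over all *other*
    subjects (leave-one-out median).
    """
    X = np.asarray(edge_matrix, dtype=np.float64)
    n = X.shape[0]
    scores = np.empty(n)
    for i in range(n):
        med = np.median(np.delete(X, i, axis=0), axis=0)
        scores[i] = _pearson(X[i], med)
    return scores


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((a @ b) / denom)


def flag_outlier_subjects(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Flag subjects whose edge-weight distribution is aberrant.

    A subject's score is its correlation with the leave-one-out median
    connectome; subjects below ``Q1 - 1.5 IQR`` of the score distribution
    are flagged.  The fence is computed on the Fisher-z (variance
    stabilized) scale, which tempers the left skew correlation scores
    carry; the reported score stays on the correlation scale.  Flags are
    reported; exclusion is left to the caller.
    """
    if len(matrices) < 4:
        raise ConnectomeError("outlier flagging needs >= 4 subjects (quartile fence)")
    X = np.vstack([vectorize(m) for m in matrices])
    scores = outlier_scores(X)
    z = np.arctanh(np.clip(scores, -R_CLAMP, R_CLAMP))
    q1, q3 = np.percentile(z, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in matrices],
            "score": scores,
            "flag": z < fence,
        }
    )


# ---------------------------------------------------------------------------
# File I/O: square delimited-text matrices and cohort-level edge tables.

def read_matrix(path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square whitespace- or comma-delimited matrix file."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    values = np.loadtxt(path, delimiter=delim)
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(path))[0]
    return ConnectivityMatrix(subject_id, values)


def write_matrix(matrix: ConnectivityMatrix, path, diagonal: float = 0.0) -> None:
    """Write a square tab-delimited matrix file (diagonal placeholder 0)."""
    v = matrix.values.copy()
    np.fill_diagonal(v, diagonal)
    np.savetxt(path, v, fmt="%.10g", delimiter="\t")


def read_edge_table(path) -> tuple[list[str], np.ndarray, int]:
    """Read a cohort edge-vector table (rows subjects, columns ``i_j`` edges).

    Returns (subject_ids, edge_matrix, n_nodes).  Columns must be the full
    canonical edge set for some node count, in canonical order.
    """
    t = pd.read_csv(path, sep="\t")
    if t.columns[0] != "subject_id":
        raise ConnectomeError("edge table must start with a subject_id column")
    n_nodes = n_nodes_for(t.shape[1] - 1)
    expected = edge_names(n_nodes)
    if list(t.columns[1:]) != expected:
        raise ConnectomeError("edge table columns are not the canonical i_j edge names")
    ids = t["subject_id"].astype(str).tolist()
    return ids, t.iloc[:, 1:].to_numpy(dtype=np.float64), n_nodes


def write_edge_table(subject_ids, edge_matrix: np.ndarray, path) -> None:
    X = np.asarray(edge_matrix, dtype=np.float64)
    n_nodes = n_nodes_for(X.shape[1])
    t = pd.DataFrame(X, columns=edge_names(n_nodes))
    t.insert(0, "subject_id", list(subject_ids))
    t.to_csv(path, sep="\t", index=False, float_format="%.10g")
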