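"""Individual structural covariance network (SCN) construction.

Two estimators are provided:

* REF-SCN -- the individual's contribution to a healthy reference group's
  region x region Pearson correlation matrix:
  ``W = corr(reference + individual) - corr(reference)``.  Entries lie in
  [-2, 2]; the sign convention is "positive = the individual increases the
  reference correlation".
* KLS-SCN -- for each parcel pair of a single subject, the symmetric
  Kullback-Leibler divergence between Gaussian kernel density estimates of
  the two parcels' voxel-wise GMV distributions, evaluated on a shared
  per-pair grid.  Entries are non-negative.

Both yield symmetric zero-diagonal d x d matrices; models consume the
row-major upper-triangle vectorization of length d(d-1)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gmv import RegionalGMVTable
from .synthgen import AtlasSpec, ParcellatedSubject

__all__ = [
    "SCNMatrix",
    "DensityEstimate",
    "harmonize_sites",
    "group_scn",
    "ref_scn_individual",
    "silverman_bandwidth",
    "estimate_pdf",
    "kls_divergence",
    "kls_scn_individual",
    "vectorize_edges",
    "devectorize",
    "edge_names",
    "write_scn_tsv",
    "write_edge_table",
]

GRID_SIZE = 128
DENSITY_FLOOR = 1e-12


@dataclass
class SCNMatrix:
    """Symmetric zero-diagonal network for one subject.

    ``kind`` is "REF" (correlation differences, in [-2, 2]) or "KLS"
    (non-negative divergences).
    """

    matrix: np.ndarray
    kind: str
    subject_id: str = ""

    def __post_init__(self):
        W = np.asarray(self.matrix, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("SCN matrix must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("SCN matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0, atol=1e-10):
            raise ValueError("SCN matrix must have a zero diagonal")
        if self.kind not in ("REF", "KLS"):
            raise ValueError("kind must be 'REF' or 'KLS'")
        if self.kind == "KLS" and np.any(W < -1e-10):
            raise ValueError("KLS networks must be non-negative")
        self.matrix = W

    @property
    def d(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DensityEstimate:
    """Discrete probability mass on a strictly increasing support grid."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mass must be positive everywhere (floored)")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1")
        self.grid, self.mass = g, m


# ---------------------------------------------------------------------------
# site harmonization and group networks

def harmonize_sites(reference: RegionalGMVTable) -> RegionalGMVTable:
    """Align each site's per-parcel mean to the pooled grand mean.

    Additive per-site offsets only; within-site variances are untouched and
    the pooled grand mean is preserved.
    """
    sites = reference.meta["site"].to_numpy()
    for s in np.unique(sites):
        if (sites == s).sum() < 2:
            raise ValueError(f"site {s} has fewer than 2 subjects")
    X = reference.values.copy()
    grand = X.mean(axis=0)
    for s in np.unique(sites):
        m = sites == s
        X[m] += grand - X[m].mean(axis=0)
    data = pd.DataFrame(X, index=reference.data.index,
                        columns=reference.data.columns)
    return RegionalGMVTable(data, reference.meta.copy())


def _corr(X: np.ndarray, context: str) -> np.ndarray:
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance parcel(s) {dead.tolist()} in {context}")
    return np.corrcoef(X, rowvar=False)


def group_scn(table: RegionalGMVTable) -> SCNMatrix:
    """Group SCN: pairwise Pearson correlation of parcels across subjects."""
    if table.n < 3:
        raise ValueError("group SCN needs at least 3 subjects")
    R = _corr(table.values, "group SCN")
    np.fill_diagonal(R, 0.0)
    return SCNMatrix(R, kind="REF", subject_id="__group__")


def ref_scn_individual(individual: np.ndarray,
                       reference: RegionalGMVTable | np.ndarray,
                       subject_id: str = "") -> SCNMatrix:
    """Reference-contribution SCN for one individual.

    ``W = corr(reference rows + individual row) - corr(reference rows)``.
    The reference should already be site-harmonized.
    """
    ref = reference.values if isinstance(reference, RegionalGMVTable) \
        else np.asarray(reference, dtype=float)
    ind = np.asarray(individual, dtype=float).ravel()
    if ind.size != ref.shape[1]:
        raise ValueError("individual length does not match reference parcels")
    if ref.shape[0] < 3:
        raise ValueError("reference needs at least 3 subjects")
    R_ref = _corr(ref, "reference table")
    R_aug = _corr(np.vstack([ref, ind]), "augmented table")
    W = R_aug - R_ref
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0  # symmetrize away float asymmetry
    return SCNMatrix(W, kind="REF", subject_id=subject_id)


# ---------------------------------------------------------------------------
# kernel density estimation and symmetric KL divergence

def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero spread: cannot form a density estimate")
    return 0.9 * spread * n ** (-0.2)


def estimate_pdf(voxel_values: np.ndarray, grid: np.ndarray,
                 bandwidth: float | None = None) -> DensityEstimate:
    """Gaussian-kernel density on ``grid``, floored and renormalized.

    The bandwidth defaults to Silverman's rule on the input values.  The
    returned object is a discrete probability mass over the grid points
    (density values normalized to sum to one), with every point floored at
    a small epsilon so that divergences are finite.
    """
    x = np.asarray(voxel_values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    g = np.asarray(grid, dtype=float)
    dens = np.exp(-0.5 * ((g[:, None] - x[None, :]) / h) ** 2).mean(axis=1)
    dens /= h * math.sqrt(2.0 * math.pi)
    dens = np.maximum(dens, DENSITY_FLOOR)
    return DensityEstimate(g, dens / dens.sum())


def kls_divergence(p: DensityEstimate, q: DensityEstimate) -> float:
    """Symmetric KL divergence KL(p||q) + KL(q||p) over shared grid mass."""
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("density estimates are on different grids")
    lr = np.log(p.mass / q.mass)
    return float(np.sum(p.mass * lr) - np.sum(q.mass * lr))


def _pair_grid(xi: np.ndarray, xj: np.ndarray, grid_size: int) -> np.ndarray:
    pooled = np.concatenate([xi, xj])
    h = silverman_bandwidth(pooled)
    lo = pooled.min() - 3.0 * h
    hi = pooled.max() + 3.0 * h
    return np.linspace(lo, hi, grid_size)


def kls_scn_individual(subject: ParcellatedSubject,
                       atlas: AtlasSpec | None = None,
                       grid_size: int = GRID_SIZE) -> SCNMatrix:
    """Per-subject KLS-SCN: pairwise symmetric KL divergences between the
    voxel-GMV densities of every parcel pair, each on a shared per-pair
    grid spanning the pooled range extended by three pooled bandwidths."""
    pids = sorted(subject.voxels) if atlas is None \
        else [int(p) for p in atlas.parcel_ids]
    vals = []
    for pid in pids:
        x = np.asarray(subject.voxels[pid], dtype=float)
        if x.size < 2 or x.std() == 0:
            raise ValueError(
                f"subject {subject.subject_id}: parcel {pid} has a "
                "degenerate voxel distribution")
        vals.append(x)
    bw = [silverman_bandwidth(x) for x in vals]
    d = len(pids)
    W = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            g = _pair_grid(vals[i], vals[j], grid_size)
            p = estimate_pdf(vals[i], g, bandwidth=bw[i])
            q = estimate_pdf(vals[j], g, bandwidth=bw[j])
            W[i, j] = W[j, i] = kls_divergence(p, q)
    return SCNMatrix(W, kind="KLS", subject_id=subject.subject_id)


# ---------------------------------------------------------------------------
# edge vectorization

def vectorize_edges(W: SCNMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle vectorization: (0,1),(0,2),...,(d-2,d-1)."""
    M = W.matrix if isinstance(W, SCNMatrix) else np.asarray(W, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("edge vectorization needs a symmetric square matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def devectorize(v: np.ndarray, d: int, kind: str = "REF",
                subject_id: str = "") -> SCNMatrix:
    """Inverse of :func:`vectorize_edges`."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != d * (d - 1) // 2:
        raise ValueError(
            f"edge vector length {v.size} != d(d-1)/2 = {d * (d - 1) // 2}")
    W = np.zeros((d, d))
    iu = np.triu_indices(d, k=1)
    W[iu] = v
    W += W.T
    return SCNMatrix(W, kind=kind, subject_id=subject_id)


def edge_names(d: int) -> list:
    iu = np.triu_indices(d, k=1)
    return [f"{i}_{j}" for i, j in zip(*iu)]


def write_scn_tsv(W: SCNMatrix, atlas: AtlasSpec, path) -> None:
    df = pd.DataFrame(W.matrix, index=list(atlas.parcel_names),
                      columns=list(atlas.parcel_names))
    df.to_csv(Path(path), sep="\t")


def write_edge_table(edge_matrix: np.ndarray, subject_ids, d: int,
                     path) -> None:
    """One row per subject, columns keyed 'i_j' in vectorization order."""
    df = pd.DataFrame(edge_matrix, index=subject_ids, columns=edge_names(d))
    df.index.name = "subject_id"
    df.to_csv(Path(path), sep="\t")
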