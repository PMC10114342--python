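"""Connectopic mapping core: connectivity fingerprints, eta-squared similarity,
graph construction, and Laplacian eigenmaps.

The method turns a (ROI, target) pair of masked BOLD time series into one or
more spatially continuous connectivity gradients:

1. Each ROI voxel gets a *connectivity fingerprint* — its Pearson correlations
   with the target time series, computed in an SVD-compressed basis for
   efficiency.
2. Fingerprints are compared pairwise with the eta-squared similarity,
   yielding a V_roi x V_roi similarity matrix.
3. The similarity matrix is sparsified into a connected k-nearest-neighbor
   graph.
4. The generalized eigenproblem L v = lambda D v of the graph Laplacian is
   solved; eigenvectors of the smallest nonzero eigenvalues are the gradients,
   min-max normalized to [0, 1]. The dominant gradient is the one with the
   smallest nonzero eigenvalue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import BoldData

log = logging.getLogger("connectograd")

_EIGENVALUE_TIE_RTOL = 1e-9


@dataclass
class Fingerprints:
    """SVD-compressed connectivity fingerprints of the ROI voxels.

    ``components`` holds, per ROI voxel, the Pearson correlation of its series
    with each retained temporal SVD component of the target data, scaled by the
    component's singular value. This compression preserves Euclidean geometry
    among the raw (per-target-voxel) correlation fingerprints. The eta-squared
    measure additionally depends on each fingerprint's grand mean, which is not
    preserved by the rotation, so the raw-space row mean (``raw_mean``, the
    correlation of each ROI series with the target mean series averaged over
    target voxels) and the raw fingerprint length (``n_raw``) are carried
    alongside; similarity computed from this object is then exactly the
    similarity of the uncompressed fingerprints whenever no variance is
    discarded.
    """

    components: np.ndarray       # V_roi x C
    singular_values: np.ndarray  # C
    raw_mean: np.ndarray         # V_roi
    n_raw: int                   # raw fingerprint length (target voxel count)

    def __post_init__(self):
        if not np.all(np.isfinite(self.components)):
            raise ValueError("fingerprints contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class GradientMap:
    """One connectivity gradient: a scalar in [0, 1] per ROI voxel."""

    values: np.ndarray
    eigenvalue: float
    index: int = 1            # 1 = dominant (smallest nonzero eigenvalue)
    sign_flipped: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("gradient values must be a vector")

    def flipped(self) -> "GradientMap":
        return replace(self, values=1.0 - self.values,
                       sign_flipped=not self.sign_flipped)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def compute_fingerprints(roi: BoldData, target: BoldData,
                         variance_kept: float = 1.0) -> Fingerprints:
    """Correlate ROI voxel series with the SVD components of the target data.

    Components are retained until their cumulative squared-singular-value
    fraction reaches ``variance_kept`` (capped at the numerical rank; at the
    default 1.0 the compression is lossless up to rank).
    """
    if roi.n_timepoints != target.n_timepoints:
        raise ValueError(
            f"ROI has T={roi.n_timepoints} but target has T={target.n_timepoints}"
        )
    if not (0.0 < variance_kept <= 1.0):
        raise ValueError("variance_kept must be in (0, 1]")
    t = roi.n_timepoints
    xt = _zscore_columns(target.series)
    if not np.any(xt):
        raise ValueError("target data are all zero (or constant)")
    z = _zscore_columns(roi.series)

    u, s, _ = np.linalg.svd(xt, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(xt.shape) * np.finfo(float).eps))
    frac = np.cumsum(s**2) / np.sum(s**2)
    c = int(np.searchsorted(frac, variance_kept - 1e-12) + 1)
    c = min(max(c, 1), rank)

    comps = (z.T @ u[:, :c]) / t * s[:c]
    raw_mean = (z.T @ xt.mean(axis=1)) / t
    log.debug("fingerprints: kept %d/%d components (%.4f variance)",
              c, rank, float(frac[c - 1]))
    return Fingerprints(comps, s[:c].copy(), raw_mean, target.n_voxels)


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Eta-squared similarity between two fingerprint vectors.

    eta^2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
                / sum_i[(a_i - M)^2 + (b_i - M)^2]

    with m_i = (a_i + b_i)/2 the elementwise pair mean and M the mean of all
    elements of a and b together. Ranges over [0, 1]; 1 means identical
    profiles. If the denominator vanishes (both vectors constant and equal to
    M), the similarity is 1 when a == b elementwise and an error otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("fingerprints must have equal length >= 2")
    m = (a + b) / 2.0
    big_m = m.mean()
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - big_m) ** 2 + (b - big_m) ** 2)
    if den <= 0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("degenerate eta-squared denominator for unequal inputs")
    return float(1.0 - num / den)


def similarity_matrix(fp: Fingerprints | np.ndarray) -> np.ndarray:
    """Pairwise eta-squared similarity between all ROI voxel fingerprints.

    Accepts either a raw fingerprint matrix (V_roi x n_features) or a
    :class:`Fingerprints` object, in which case distances and norms come from
    the compressed representation while the grand-mean term uses the exact
    raw-space row means and raw length (see :class:`Fingerprints`).
    """
    if isinstance(fp, Fingerprints):
        f = fp.components
        n = fp.n_raw
        row_sum = fp.raw_mean * n
    else:
        f = np.asarray(fp, dtype=float)
        n = f.shape[1]
        row_sum = f.sum(axis=1)
    sq = np.einsum("ij,ij->i", f, f)
    gram = f @ f.T
    num = sq[:, None] + sq[None, :] - 2.0 * gram      # ||a-b||^2
    np.fill_diagonal(num, 0.0)
    big_m = (row_sum[:, None] + row_sum[None, :]) / (2.0 * n)
    den = sq[:, None] + sq[None, :] - 2.0 * n * big_m**2
    bad = den <= 0
    if bad.any():
        if np.any(bad & (num > 1e-24)):
            raise ValueError("degenerate eta-squared denominator for unequal rows")
        den = np.where(bad, 1.0, den)
        num = np.where(bad, 0.0, num)
    s = 1.0 - (num / 2.0) / den
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    _check_similarity(s)
    return s


def _check_similarity(s: np.ndarray) -> None:
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(s), 1.0, atol=1e-10):
        raise ValueError("similarity matrix diagonal must be 1")
    if s.min() < -1e-12 or s.max() > 1 + 1e-12:
        raise ValueError("similarity entries must lie in [0, 1]")


def build_graph(s: np.ndarray, k_neighbors: int = 8,
                dense: bool = False) -> tuple[np.ndarray, int]:
    """Sparsify a similarity matrix into a connected weighted graph.

    Keeps, for each voxel, its ``k_neighbors`` most similar neighbors
    (symmetric union), with eta-squared values as edge weights. If the result
    is disconnected, k is incremented until it connects (logged). With
    ``dense=True`` the full off-diagonal similarity is used as the adjacency.

    Returns ``(adjacency, k_used)``; ``k_used`` is 0 in dense mode.
    """
    _check_similarity(s)
    v = s.shape[0]
    if v < 2:
        raise ValueError("similarity matrix must be at least 2x2")
    if dense:
        w = s.copy()
        np.fill_diagonal(w, 0.0)
        return w, 0
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    k = min(k_neighbors, v - 1)
    while True:
        order = np.argsort(-s, axis=1)
        keep = np.zeros_like(s, dtype=bool)
        rows = np.arange(v)[:, None]
        neigh = order[:, 1:k + 1]  # skip self (diagonal is the max, 1.0)
        keep[rows, neigh] = True
        keep |= keep.T
        w = np.where(keep, s, 0.0)
        np.fill_diagonal(w, 0.0)
        n_comp, _ = connected_components(csr_matrix(w), directed=False)
        if n_comp == 1 or k >= v - 1:
            if n_comp > 1:
                raise ValueError("graph disconnected even at full k")
            if k != k_neighbors:
                log.info("build_graph: escalated k from %d to %d for connectivity",
                         k_neighbors, k)
            return w, k
        k += 1


def laplacian_eigenmaps(w: np.ndarray, n_gradients: int = 1) -> list[GradientMap]:
    """Solve L v = lambda D v on the graph and return the leading gradients.

    L = D - W is the graph Laplacian and D the degree diagonal. The trivial
    constant eigenvector (lambda = 0) is discarded; the eigenvectors of the
    ``n_gradients`` smallest nonzero eigenvalues are returned, each min-max
    normalized to [0, 1]. Solved in symmetric-normalized form
    (D^-1/2 L D^-1/2) u = lambda u with v = D^-1/2 u, which is equivalent for
    connected graphs with positive degrees.
    """
    w = np.asarray(w, dtype=float)
    v = w.shape[0]
    if w.ndim != 2 or w.shape[1] != v:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if w.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = w.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("graph has isolated nodes (zero degree): not connected")
    n_comp, _ = connected_components(csr_matrix(w), directed=False)
    if n_comp > 1:
        raise ValueError(f"graph is disconnected ({n_comp} components)")
    if n_gradients < 1 or n_gradients > v - 1:
        raise ValueError("n_gradients must be in [1, V-1]")

    d_isqrt = 1.0 / np.sqrt(deg)
    lsym = -(w * d_isqrt[:, None]) * d_isqrt[None, :]
    np.fill_diagonal(lsym, 1.0 + np.diag(lsym))
    evals, evecs = np.linalg.eigh(lsym)

    # drop the trivial lambda=0 eigenvector; guard against numerically tiny
    # second eigenvalues that indicate near-disconnection
    scale = max(abs(evals[-1]), 1.0)
    if evals[1] <= 1e-12 * scale:
        raise ValueError("second eigenvalue is ~0: graph effectively disconnected")
    gaps = np.diff(evals[1:1 + n_gradients + 1]) if v > n_gradients + 1 else []
    if np.any(np.asarray(gaps) <= _EIGENVALUE_TIE_RTOL * scale):
        log.warning("laplacian_eigenmaps: (near-)degenerate eigenvalues; "
                    "returned gradients are not unique")

    out = []
    for i in range(n_gradients):
        vec = d_isqrt * evecs[:, 1 + i]
        lo, hi = vec.min(), vec.max()
        if hi - lo <= 0:
            raise ValueError("constant nonzero-eigenvalue eigenvector: "
                             "graph effectively disconnected")
        out.append(GradientMap((vec - lo) / (hi - lo), float(evals[1 + i]), i + 1))
    return out


def align_sign(g: GradientMap, reference: GradientMap | np.ndarray) -> GradientMap:
    """Flip a gradient (value -> 1-value) iff it anti-correlates with the reference.

    Eigenvector signs are arbitrary; any comparison of gradient *direction*
    must first fix the orientation.
    """
    ref = reference.values if isinstance(reference, GradientMap) else np.asarray(reference, float)
    if ref.shape != g.values.shape:
        raise ValueError("gradient and reference must share the voxel set")
    if np.ptp(g.values) == 0 or np.ptp(ref) == 0:
        raise ValueError("zero-variance gradient cannot be sign-aligned")
    r = float(np.corrcoef(g.values, ref)[0, 1])
    return g.flipped() if r < 0 else g


def orient_to_axis(g: GradientMap, coords: np.ndarray,
                   axis: int = 2) -> GradientMap:
    """Orient a gradient so its values increase along a world axis (default z).

    Fallback sign convention when no reference gradient is available.
    """
    c = np.asarray(coords, dtype=float)[:, axis]
    if c.std() == 0:
        return g
    return align_sign(g, (c - c.min()) / max(c.max() - c.min(), 1e-300))


def group_gradient(gradients: list[GradientMap]) -> GradientMap:
    """Voxelwise mean of sign-aligned gradients, renormalized to [0, 1].

    Each gradient is aligned to the running mean (initialized at the first),
    then averaged.
    """
    if len(gradients) == 0:
        raise ValueError("need at least one gradient")
    n_vox = gradients[0].values.shape[0]
    for g in gradients:
        if g.values.shape[0] != n_vox:
            raise ValueError("gradients must share the voxel set")
    acc = gradients[0].values.copy()
    for i, g in enumerate(gradients[1:], start=2):
        aligned = align_sign(g, acc / (i - 1))
        acc += aligned.values
    mean = acc / len(gradients)
    lo, hi = mean.min(), mean.max()
    if hi - lo <= 0:
        raise ValueError("degenerate (constant) group gradient")
    vals = (mean - lo) / (hi - lo)
    return GradientMap(vals, float(np.mean([g.eigenvalue for g in gradients])), 1)


def connectopic_gradients(roi: BoldData, target: BoldData,
                          n_gradients: int = 1, k_neighbors: int = 8,
                          variance_kept: float = 1.0, dense: bool = False,
                          reference: GradientMap | np.ndarray | None = None,
                          ) -> tuple[list[GradientMap], dict]:
    """Run the full connectopic-mapping chain on a (ROI, target) pair.

    Returns the gradients (dominant first) and an info dict with the
    eigenvalues, the k actually used for the graph, and sign flips. The
    dominant gradient is oriented to the ``reference`` if given, otherwise so
    that it increases with the world z coordinate.
    """
    fp = compute_fingerprints(roi, target, variance_kept)
    s = similarity_matrix(fp)
    w, k_used = build_graph(s, k_neighbors, dense=dense)
    grads = laplacian_eigenmaps(w, n_gradients)
    coords = roi.coords_world()
    oriented = []
    for g in grads:
        if reference is not None:
            oriented.append(align_sign(g, reference))
        else:
            oriented.append(orient_to_axis(g, coords))
    info = {
        "eigenvalues": [g.eigenvalue for g in oriented],
        "k_used": k_used,
        "n_components": fp.n_components,
        "sign_flipped": [g.sign_flipped for g in oriented],
    }
    return oriented, info
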