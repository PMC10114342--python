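"""Trend-surface modeling: polynomial spatial regression of gradient values.

A gradient map is summarized by regressing its per-voxel values on polynomial
basis functions of the voxel world coordinates (x, y, z and their powers, no
cross terms). At order 3 this yields nine spatial coefficients — the
quantities carried into all cohort statistics — plus an intercept handled
internally and the fraction of spatial variance explained.

The fit is Bayesian linear regression with a zero-mean isotropic Gaussian
prior on the spatial coefficients; the prior precision (alpha) and noise
precision (beta) are set by evidence maximization (type-II maximum
likelihood, MacKay fixed-point iteration). Coordinates are standardized per
axis before powering to keep the design well-conditioned and the coefficients
comparable across subjects sharing a mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientMap

log = logging.getLogger("connectograd")

_AXES = "xyz"


@dataclass
class TSMBasis:
    """Polynomial design over standardized world coordinates.

    Columns are ordered x, y, z, x^2, y^2, z^2, ..., up to the model order.
    Degenerate axes (all voxels sharing one coordinate) yield zeroed columns
    and are flagged.
    """

    order: int
    matrix: np.ndarray            # V x 3*order
    names: list[str]
    degenerate_axes: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TSMModel:
    """Fitted trend-surface model."""

    order: int
    coefficients: np.ndarray      # 3*order, matching basis names
    names: list[str]
    intercept: float
    alpha: float                  # coefficient-prior precision
    beta: float                   # noise precision
    var_explained: float
    log_evidence: float

    def __post_init__(self):
        if not (-1e-9 <= self.var_explained <= 1 + 1e-9):
            raise ValueError("var_explained must lie in [0, 1]")
        self.var_explained = float(np.clip(self.var_explained, 0.0, 1.0))
        if len(self.names) != len(self.coefficients):
            raise ValueError("coefficient names do not match coefficients")

    def as_dict(self) -> dict:
        d = {n: float(c) for n, c in zip(self.names, self.coefficients)}
        d["var_explained"] = self.var_explained
        return d


def basis_names(order: int) -> list[str]:
    return [f"{ax}{p}" if p > 1 else ax
            for p in range(1, order + 1) for ax in _AXES]


def make_basis(coords: np.ndarray, order: int = 3) -> TSMBasis:
    """Build the per-axis monomial design from world (mm) coordinates.

    Each axis is standardized (mean 0, sd 1) and raised to powers 1..order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be V x 3 world coordinates")
    if order < 1:
        raise ValueError("order must be >= 1")
    v = coords.shape[0]
    if v < 3 * order + 1:
        raise ValueError(
            f"need at least {3 * order + 1} voxels for order {order}, got {v}"
        )
    mu = coords.mean(axis=0)
    sd = coords.std(axis=0)
    degenerate = [_AXES[i] for i in range(3) if sd[i] <= 1e-12]
    if degenerate:
        log.warning("make_basis: degenerate axis/axes %s: columns zeroed",
                    ",".join(degenerate))
    z = np.where(sd > 1e-12, (coords - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    cols = [z[:, i] ** p if sd[i] > 1e-12 else np.zeros(v)
            for p in range(1, order + 1) for i in range(3)]
    return TSMBasis(order, np.column_stack(cols), basis_names(order), degenerate)


def _log_evidence(xc: np.ndarray, yc: np.ndarray, alpha: float, beta: float) -> float:
    """Log marginal likelihood of the centered ridge model at (alpha, beta)."""
    n, m = xc.shape
    a = alpha * np.eye(m) + beta * (xc.T @ xc)
    mn = beta * np.linalg.solve(a, xc.T @ yc)
    e = beta / 2 * np.sum((yc - xc @ mn) ** 2) + alpha / 2 * np.sum(mn**2)
    sign, logdet = np.linalg.slogdet(a)
    if sign <= 0:  # pragma: no cover - a is PD by construction
        raise np.linalg.LinAlgError("non-PD evidence matrix")
    return float(m / 2 * np.log(alpha) + n / 2 * np.log(beta)
                 - e - logdet / 2 - n / 2 * np.log(2 * np.pi))


def fit_tsm(g: GradientMap | np.ndarray, basis: TSMBasis,
            max_iter: int = 300, tol: float = 1e-8) -> TSMModel:
    """Evidence-maximized Bayesian fit of gradient values on a TSM basis.

    Returns the posterior-mean coefficients, the fitted intercept, the
    optimized precisions, and var_explained = 1 - RSS/TSS of the gradient
    values.
    """
    y = g.values if isinstance(g, GradientMap) else np.asarray(g, dtype=float)
    x = basis.matrix
    n = x.shape[0]
    if y.shape != (n,):
        raise ValueError("gradient length does not match basis rows")
    active = [j for j, name in enumerate(basis.names)
              if name[0] not in basis.degenerate_axes]
    if n < len(active) + 1:
        raise ValueError("fewer voxels than model columns")
    xa = x[:, active]
    col_mu = xa.mean(axis=0)
    xc = xa - col_mu
    y_mu = y.mean()
    yc = y - y_mu
    tss = float(np.sum(yc**2))
    if tss <= 0:
        raise ValueError("constant gradient: nothing to fit")

    # MacKay fixed-point updates on the eigenbasis of Xc'Xc
    evals, evecs = np.linalg.eigh(xc.T @ xc)
    evals = np.clip(evals, 0.0, None)
    xty = evecs.T @ (xc.T @ yc)
    m_eff = len(active)
    alpha, beta = 1e-6, 1.0 / max(yc.var(), 1e-12)
    for _ in range(max_iter):
        d = alpha + beta * evals
        coef = evecs @ (beta * xty / d)      # posterior mean
        rss = float(np.sum((yc - xc @ coef) ** 2))
        gamma = float(np.sum(beta * evals / d))
        alpha_new = gamma / max(float(np.sum(coef**2)), 1e-300)
        beta_new = max(n - gamma, 1e-12) / max(rss, 1e-300)
        if (abs(alpha_new - alpha) <= tol * max(alpha, 1.0)
                and abs(beta_new - beta) <= tol * max(beta, 1.0)):
            alpha, beta = alpha_new, beta_new
            break
        alpha, beta = alpha_new, beta_new
    coef = evecs @ (beta * xty / (alpha + beta * evals))
    rss = float(np.sum((yc - xc @ coef) ** 2))
    var_explained = max(0.0, 1.0 - rss / tss)

    full_coef = np.zeros(x.shape[1])
    full_coef[active] = coef
    intercept = float(y_mu - col_mu @ coef)
    return TSMModel(basis.order, full_coef, list(basis.names), intercept,
                    float(alpha), float(beta), var_explained,
                    _log_evidence(xc, yc, alpha, beta))


def variance_profile(g: GradientMap | np.ndarray, coords: np.ndarray,
                     m_max: int = 3) -> list[float]:
    """Explained variance of independently fitted models of order 1..m_max."""
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    return [fit_tsm(g, make_basis(coords, m)).var_explained
            for m in range(1, m_max + 1)]
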