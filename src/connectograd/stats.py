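"""Cohort statistics over trend-surface parameters.

Covariate-adjusted nonparametric association tests — partial Spearman rank
correlations for continuous outcomes and covariate-adjusted Mann-Whitney
U-tests for group contrasts — with Benjamini-Hochberg FDR correction within
each analysis family, plus the conventional scalar connectivity baselines
(intrinsic and whole-brain mean Fisher-z connectivity of a mask).

Partial Spearman is frozen to the rank-residual definition: x, y, and the
covariates are rank-transformed; ranked x and ranked y are residualized on
the ranked covariates (with intercept) by least squares; rho is the Pearson
correlation of the residuals and the p-value comes from the t approximation
with n - 2 - #covariates degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import TSM_COLUMNS, BoldData

log = logging.getLogger("connectograd")

_Z_CLIP = 1.0 - 1e-7  # correlation magnitude cap before Fisher z


@dataclass
class AnalysisSpec:
    """One family of tests: an outcome against the TSM parameters."""

    outcome: str
    test: str = "partial-spearman"  # or "adjusted-mannwhitney"
    parameters: list[str] = field(default_factory=lambda: list(TSM_COLUMNS))
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    alpha: float = 0.05

    def __post_init__(self):
        if self.test not in ("partial-spearman", "adjusted-mannwhitney"):
            raise ValueError(f"unknown test {self.test!r}")


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y on [1, covs]."""
    design = np.c_[np.ones(len(y)), covs] if covs.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman rank correlation of x and y given covariates.

    Returns (rho, two-sided p). With no covariates this reduces exactly to the
    ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covs = np.empty((len(x), 0))
    else:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
    n = len(x)
    k = covs.shape[1]
    if len(y) != n or covs.shape[0] != n:
        raise ValueError("x, y and covariates must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(covs))):
        raise ValueError("inputs must be finite")
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant variable after ranking")
    rc = np.column_stack([sps.rankdata(c) for c in covs.T]) if k else covs
    ex = _residualize(rx, rc)
    ey = _residualize(ry, rc)
    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom <= 0:
        raise ValueError("covariates fully explain x or y")
    rho = float(np.sum(ex * ey) / denom)
    df = n - 2 - k
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    r = min(max(rho, -_Z_CLIP), _Z_CLIP)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p


def adjusted_mannwhitney(values, groups, covariates=None,
                         adjust: bool = True) -> tuple[float, float]:
    """Mann-Whitney U-test on covariate-residualized values.

    Values are residualized on the covariates (with intercept) across all
    subjects, then the U-test compares the two groups' residuals. The exact
    null distribution is enumerated when both groups have <= 8 members;
    otherwise the normal approximation with tie correction is used.
    ``adjust=False`` skips residualization (plain Mann-Whitney).
    Returns (U of the first-labeled group, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    g0, g1 = groups == labels[0], groups == labels[1]
    n0, n1 = int(g0.sum()), int(g1.sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be nonempty")
    covs = (np.empty((len(values), 0)) if (covariates is None or not adjust)
            else np.asarray(covariates, float))
    if covs.ndim == 1:
        covs = covs[:, None]
    if len(values) < covs.shape[1] + 4:
        raise ValueError("too few observations for the covariate count")
    res = _residualize(values, covs) if covs.size else values
    method = "exact" if max(n0, n1) <= 8 else "asymptotic"
    out = sps.mannwhitneyu(res[g0], res[g1], alternative="two-sided",
                           method=method)
    return float(out.statistic), float(out.pvalue)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_analysis(cohort: pd.DataFrame, spec: AnalysisSpec) -> pd.DataFrame:
    """Run one test family over the TSM parameters and FDR-correct within it.

    Subjects flagged ``qc_pass == 0`` (if the column exists) are dropped, and
    subjects missing the outcome or a covariate are removed listwise (logged).
    Returns one row per parameter: statistic, p, q, n, sorted by q then p.
    """
    df = cohort
    if "qc_pass" in df.columns:
        n_before = len(df)
        df = df[df["qc_pass"].astype(bool)]
        if len(df) < n_before:
            log.info("run_analysis: %d subject(s) excluded by QC",
                     n_before - len(df))
    needed = [spec.outcome, *spec.covariates, *spec.parameters]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {missing_cols}")
    sub = df[needed].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < len(df):
        log.info("run_analysis: listwise deletion removed %d subject(s), n=%d",
                 len(df) - len(sub), len(sub))
    n = len(sub)
    min_n = len(spec.covariates) + (4 if spec.test == "adjusted-mannwhitney" else 3)
    if n < min_n:
        raise ValueError(f"only {n} subjects after deletion (need >= {min_n})")
    covs = sub[spec.covariates].to_numpy() if spec.covariates else None
    rows = []
    for param in spec.parameters:
        if spec.test == "partial-spearman":
            stat, p = partial_spearman(sub[param], sub[spec.outcome], covs)
        else:
            stat, p = adjusted_mannwhitney(sub[param], sub[spec.outcome], covs)
        rows.append({"parameter": param, "statistic": stat, "p": p, "n": n})
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p"].to_numpy())
    out["significant"] = out["q"] < spec.alpha
    out = out[["parameter", "statistic", "p", "q", "n", "significant"]]
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Conventional connectivity baselines

def _fisher_z(r: np.ndarray) -> tuple[np.ndarray, int]:
    r = np.asarray(r, dtype=float)
    clipped = int(np.sum(np.abs(r) > _Z_CLIP))
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP)), clipped


def intrinsic_connectivity(bold: BoldData, voxel_index: np.ndarray) -> float:
    """Mean Fisher-z of all within-mask pairwise voxel correlations."""
    idx = np.asarray(voxel_index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if len(idx) < 2:
        raise ValueError("intrinsic connectivity needs at least 2 voxels")
    x = bold.series[:, idx]
    r = np.corrcoef(x.T)
    iu = np.triu_indices(len(idx), k=1)
    z, clipped = _fisher_z(r[iu])
    if clipped:
        log.warning("intrinsic_connectivity: %d correlation(s) at the "
                    "unit boundary were clipped", clipped)
    return float(z.mean())


def wholebrain_connectivity(bold: BoldData, voxel_index: np.ndarray,
                            target: BoldData) -> float:
    """Mean Fisher-z of mask-voxel-to-target-voxel correlations."""
    idx = np.asarray(voxel_index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if len(idx) < 1:
        raise ValueError("empty mask")
    if bold.n_timepoints != target.n_timepoints:
        raise ValueError("BOLD and target must share T")
    a = bold.series[:, idx]
    a = (a - a.mean(0)) / np.where(a.std(0) > 0, a.std(0), 1.0)
    b = target.series
    b = (b - b.mean(0)) / np.where(b.std(0) > 0, b.std(0), 1.0)
    r = (a.T @ b) / bold.n_timepoints
    z, clipped = _fisher_z(r.ravel())
    if clipped:
        log.warning("wholebrain_connectivity: %d correlation(s) clipped", clipped)
    return float(z.mean())


def conventional_fc(bold: BoldData, target: BoldData,
                    masks: dict[str, np.ndarray],
                    modes: dict[str, str] | None = None) -> pd.DataFrame:
    """Scalar connectivity per named subregion mask.

    ``masks`` maps names to boolean index vectors over the BOLD mask voxels
    (or 3D boolean volumes on the BOLD grid). ``modes`` selects "intrinsic"
    or "wholebrain" per mask (default wholebrain; a mask named like the
    default-mode network defaults to intrinsic).
    """
    modes = modes or {}
    rows = []
    for name, m in masks.items():
        m = np.asarray(m)
        if m.ndim == 3:
            if m.shape != bold.grid.shape:
                raise ValueError(f"mask {name!r} shape does not match grid")
            full = np.flatnonzero(bold.mask.ravel())
            sel = np.flatnonzero(m.astype(bool).ravel())
            idx = np.searchsorted(full, sel)
            if np.any(idx >= len(full)) or np.any(full[idx] != sel):
                raise ValueError(f"mask {name!r} has voxels outside the BOLD mask")
        else:
            idx = np.flatnonzero(m) if m.dtype == bool else m.astype(int)
        mode = modes.get(name, "intrinsic" if "dmn" in name.lower()
                         else "wholebrain")
        if mode == "intrinsic":
            val = intrinsic_connectivity(bold, idx)
        elif mode == "wholebrain":
            val = wholebrain_connectivity(bold, idx, target)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"mask": name, "mode": mode, "fc_z": val,
                     "n_voxels": int(len(idx))})
    return pd.DataFrame(rows)
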