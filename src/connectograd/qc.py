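"""Subject-inclusion rules and excluded-vs-included comparability.

A subject enters the cohort statistics only if (a) their dominant gradient
preserves the main direction of the reference (group) gradient, and (b) the
trend-surface model explains at least 70% of the spatial variance of that
gradient. Gradients failing the variance gate are typically artifactual —
driven by a few outlier voxels rather than smooth connectivity change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gradients import GradientMap
from .trend import TSMModel

log = logging.getLogger("connectograd")


@dataclass
class QCReport:
    """Per-subject inclusion flags plus cohort counts."""

    flags: pd.DataFrame  # columns: subject, direction_ok, variance_ok, included

    def __post_init__(self):
        f = self.flags
        if not (f["included"] == (f["direction_ok"] & f["variance_ok"])).all():
            raise ValueError("included must equal direction_ok AND variance_ok")

    @property
    def n_included(self) -> int:
        return int(self.flags["included"].sum())

    @property
    def n_total(self) -> int:
        return len(self.flags)


def check_direction(g: GradientMap | np.ndarray,
                    reference: GradientMap | np.ndarray,
                    r_min: float = 0.5) -> bool:
    """True iff |Pearson r(gradient, reference)| >= r_min.

    The absolute value makes the check orientation-free (eigenvector sign is
    arbitrary; flipping is handled upstream by sign alignment).
    """
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie in (0, 1)")
    gv = g.values if isinstance(g, GradientMap) else np.asarray(g, float)
    rv = (reference.values if isinstance(reference, GradientMap)
          else np.asarray(reference, float))
    if gv.shape != rv.shape:
        raise ValueError("gradient and reference must share the voxel set")
    if np.ptp(gv) == 0 or np.ptp(rv) == 0:
        raise ValueError("zero-variance gradient in direction check")
    return bool(abs(np.corrcoef(gv, rv)[0, 1]) >= r_min)


def check_variance(model: TSMModel | float, threshold: float = 0.70) -> bool:
    """True iff the TSM explains at least ``threshold`` of the gradient's
    spatial variance (inclusive bound: var_explained == threshold passes)."""
    v = model.var_explained if isinstance(model, TSMModel) else float(model)
    return bool(v >= threshold)


def qc_report(subjects: list[str],
              gradients: list[GradientMap | np.ndarray],
              models: list[TSMModel | float],
              reference: GradientMap | np.ndarray,
              r_min: float = 0.5, var_min: float = 0.70) -> QCReport:
    """Apply both inclusion rules to a cohort of fitted subjects."""
    if not len(subjects) == len(gradients) == len(models):
        raise ValueError("subjects, gradients and models must align")
    rows = []
    for sid, g, m in zip(subjects, gradients, models):
        d = check_direction(g, reference, r_min)
        v = check_variance(m, var_min)
        rows.append({"subject": sid, "direction_ok": d, "variance_ok": v,
                     "included": d and v})
    report = QCReport(pd.DataFrame(rows))
    log.info("QC: %d/%d subjects included", report.n_included, report.n_total)
    return report


def compare_excluded(cohort: pd.DataFrame, included: np.ndarray,
                     continuous: list[str] | None = None,
                     binary: list[str] | None = None,
                     equal_var: bool = True) -> pd.DataFrame:
    """Compare excluded vs included subjects on demographic variables.

    Continuous variables use a two-sample Student's t-test (``equal_var=False``
    switches to Welch), binary variables Fisher's exact test. P-values are
    reported uncorrected — the comparison is descriptive. Variables with
    fewer than 2 non-missing subjects in either group are skipped with a
    warning.
    """
    included = np.asarray(included, dtype=bool)
    if len(included) != len(cohort):
        raise ValueError("included flags must align with the cohort table")
    continuous = continuous or []
    binary = binary or []
    rows = []
    for var in continuous:
        a = pd.to_numeric(cohort.loc[included, var], errors="coerce").dropna()
        b = pd.to_numeric(cohort.loc[~included, var], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            log.warning("compare_excluded: skipping %r (group too small)", var)
            continue
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"variable": var, "test": "t", "statistic": float(t),
                     "p": float(p), "n_included": len(a), "n_excluded": len(b)})
    for var in binary:
        sub = cohort[[var]].copy()
        sub["included"] = included
        sub = sub.dropna(subset=[var])
        inc = sub.loc[sub["included"], var].astype(int)
        exc = sub.loc[~sub["included"], var].astype(int)
        if len(inc) < 2 or len(exc) < 2:
            log.warning("compare_excluded: skipping %r (group too small)", var)
            continue
        table = [[int((inc == 1).sum()), int((inc == 0).sum())],
                 [int((exc == 1).sum()), int((exc == 0).sum())]]
        odds, p = sps.fisher_exact(table)
        rows.append({"variable": var, "test": "fisher", "statistic": float(odds),
                     "p": float(p), "n_included": len(inc),
                     "n_excluded": len(exc)})
    return pd.DataFrame(rows,
                        columns=["variable", "test", "statistic", "p",
                                 "n_included", "n_excluded"])
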