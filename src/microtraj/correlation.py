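"""Covariate-adjusted semi-partial Spearman correlation with outlier removal.

The association between a species' relative abundance and a clinical
readout (plane distance, serum cytokine, arthritis score) is measured by a
semi-partial (part) Spearman correlation: all variables are rank
transformed (average ranks on ties), the covariate ranks are regressed out
of the abundance ranks by least squares, and the residuals are correlated
with the outcome ranks (Pearson on ranks).  Covariates are removed from
the abundance variable only, so the coefficient reads as "what the microbe
adds beyond weight/group/score".  Significance uses the t approximation
with n - k - 2 degrees of freedom for k covariate columns.

Outliers are removed pairwise before adjustment using Tukey fences
(1.5 x IQR beyond the quartiles, per variable); with fewer than 8 pairs no
removal is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .profiles import AbundanceProfile, SampleMetadata

__all__ = [
    "CorrelationResult",
    "CorrelationError",
    "remove_outliers",
    "semipartial_spearman",
    "correlate_panel",
    "build_covariates",
]


class CorrelationError(ValueError):
    """Invalid input to the correlation machinery."""


@dataclass
class CorrelationResult:
    """A single adjusted correlation: coefficient, p, bookkeeping."""

    x_name: str
    y_name: str
    covariates: tuple
    coefficient: float
    p_value: float
    n_used: int
    n_removed_outliers: int = 0
    degenerate: bool = False
    q_value: float | None = None


def remove_outliers(x, y, min_n: int = 8) -> np.ndarray:
    """Indices of pairs inside the Tukey 1.5*IQR fences of both variables.

    Quartiles use linear interpolation.  With fewer than ``min_n`` pairs no
    removal is attempted (fences are meaningless at very small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < min_n:
        return np.arange(n)
    keep = np.ones(n, dtype=bool)
    for v in (x, y):
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep &= (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return np.flatnonzero(keep)


def _rank(v: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(v, method="average")


def semipartial_spearman(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple = (),
    adjust: str = "x",
) -> CorrelationResult:
    """Semi-partial Spearman correlation of ``x`` with ``y``.

    Covariates (an n x k matrix, dummy-coded factors included) are rank
    transformed and regressed out of ``x``'s ranks (or ``y``'s with
    ``adjust="y"``); the residuals are Pearson-correlated with the other
    variable's ranks.  Zero-variance inputs yield a flagged degenerate
    result instead of an exception; rank-deficient covariates raise.
    """
    if adjust not in ("x", "y"):
        raise CorrelationError(f"adjust must be 'x' or 'y', got {adjust!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise CorrelationError("covariates have inconsistent sample count")
    k = cov.shape[1]
    if n < k + 3:
        raise CorrelationError(f"need n >= {k + 3} samples for {k} covariates, got {n}")
    names = tuple(covariate_names) if covariate_names else tuple(f"c{j}" for j in range(k))

    rx, ry = _rank(x), _rank(y)
    if rx.std() == 0 or ry.std() == 0:
        return CorrelationResult(
            x_name, y_name, names, float("nan"), float("nan"), n, 0, degenerate=True
        )
    target, other = (rx, ry) if adjust == "x" else (ry, rx)
    # constant covariates are collinear with the intercept and remove
    # nothing; drop them rather than failing the rank check
    varying = [j for j in range(k) if np.ptp(cov[:, j]) > 0]
    if varying:
        rc = np.column_stack([_rank(cov[:, j]) for j in varying])
        design = np.column_stack([np.ones(n), rc])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CorrelationError("covariates are rank-deficient after dummy coding")
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ coef
    else:
        resid = target - target.mean()
    if resid.std() == 0:
        return CorrelationResult(
            x_name, y_name, names, float("nan"), float("nan"), n, 0, degenerate=True
        )
    oc = other - other.mean()
    cc = float(resid @ oc / (np.linalg.norm(resid) * np.linalg.norm(oc)))
    cc = min(1.0, max(-1.0, cc))
    df = n - k - 2
    if df <= 0:
        raise CorrelationError("not enough degrees of freedom for a p-value")
    if abs(cc) >= 1.0:
        p = 0.0
    else:
        t = cc * np.sqrt(df / (1.0 - cc * cc))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return CorrelationResult(x_name, y_name, names, cc, p, n, 0)


def build_covariates(meta_frame: pd.DataFrame, names) -> tuple[np.ndarray, tuple]:
    """Assemble a covariate matrix from metadata columns.

    Numeric columns enter as-is; the ``group`` factor is dummy-coded with
    the first group (in order of appearance) as the reference level.
    Returns (matrix, column names).
    """
    cols = []
    out_names = []
    for name in names:
        if name not in meta_frame.columns:
            raise CorrelationError(f"unknown covariate {name!r}")
        col = meta_frame[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(dict.fromkeys(col))
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                out_names.append(f"{name}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            out_names.append(name)
    matrix = np.column_stack(cols) if cols else np.empty((len(meta_frame), 0))
    return matrix, tuple(out_names)


def correlate_panel(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    targets,
    covariates=("weight", "group"),
    species=None,
    distance_series=None,
    outlier_rule: str = "tukey",
    bh_adjust: bool = False,
) -> list[CorrelationResult]:
    """Adjusted correlations of species abundances against clinical targets.

    ``targets`` names metadata columns (cytokines, arthritis_score, ...) or
    plane-distance columns of an optional ``distance_series``.  Outlier
    removal (Tukey fences, ``outlier_rule="none"`` disables it) is applied
    pairwise to each (abundance, target) pair before adjustment.  With
    ``bh_adjust`` a Benjamini-Hochberg q-value is attached across the
    panel (no correction is applied to the reported p-values themselves).
    """
    if outlier_rule not in ("tukey", "none"):
        raise CorrelationError(f"unknown outlier rule {outlier_rule!r}")
    meta.validate_against(profile)
    m = meta.aligned_to(profile.sample_ids)
    if species is None:
        species = profile.species_ids
    else:
        missing = [s for s in species if s not in profile.data.columns]
        if missing:
            raise CorrelationError(f"species not in profile: {missing[:5]}")
    target_values = {}
    for t in targets:
        if t in m.columns:
            target_values[t] = m[t].to_numpy(dtype=float)
        elif distance_series is not None and t in distance_series.data.columns:
            target_values[t] = (
                distance_series.data[t].reindex(profile.sample_ids).to_numpy(dtype=float)
            )
        else:
            raise CorrelationError(f"unknown target {t!r}")
    cov_all, cov_names = build_covariates(m, covariates)
    results = []
    for s in species:
        x_all = profile.data[s].to_numpy(dtype=float)
        for t, y_all in target_values.items():
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            x, y, cov = x_all[ok], y_all[ok], cov_all[ok]
            if outlier_rule == "tukey":
                kept = remove_outliers(x, y)
            else:
                kept = np.arange(x.size)
            removed = x.size - kept.size
            res = semipartial_spearman(
                x[kept],
                y[kept],
                cov[kept],
                x_name=s,
                y_name=t,
                covariate_names=cov_names,
            )
            res.n_removed_outliers = removed
            results.append(res)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ps = np.array([r.p_value for r in results])
        finite = np.isfinite(ps)
        if finite.any():
            q = np.full(ps.shape, np.nan)
            q[finite] = multipletests(ps[finite], method="fdr_bh")[1]
            for r, qv in zip(results, q):
                r.q_value = float(qv) if np.isfinite(qv) else None
    return results
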