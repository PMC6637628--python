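"""Bray-Curtis ordination and health/disease-plane trajectory distances.

The dysbiosis summary works in three steps.  First, pairwise Bray-Curtis
dissimilarities between all samples are embedded by classical principal
coordinates analysis (PCoA).  Second, within the first three principal
coordinates, the samples of the untreated healthy group and of the disease
group are each fitted with a two-dimensional plane at every time point —
the "healthy plane" (HP) and "disease plane" (DP) — by orthogonal (total)
least squares.  Third, every sample's Euclidean distance to both planes is
recorded; the HP/DP distance pair tracks how far a community has moved from
the healthy state toward the diseased one.  A paired t test compares the
two distances within a group at a time point, and a covariate-adjusted
semi-partial Spearman correlation relates plane distance to the clinical
arthritis score.

One joint PCoA is computed over all samples, groups and time points so that
distances from treated samples to both planes live in a single shared
coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import scipy.stats

from .profiles import AbundanceProfile, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "PCoAEmbedding",
    "PlaneModel",
    "DistanceSeries",
    "PairedTResult",
    "OrdinationError",
    "PlaneFitError",
    "bray_curtis",
    "pcoa",
    "fit_plane",
    "distance_to_plane",
    "plane_distance_series",
    "paired_t",
    "score_plane_correlation",
]


class OrdinationError(ValueError):
    """Invalid input to the ordination / plane machinery."""


class PlaneFitError(ValueError):
    """Degenerate point set for plane fitting."""


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with sample labels."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise OrdinationError("distance matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise OrdinationError("sample_ids length does not match matrix size")
        if not np.isfinite(v).all():
            raise OrdinationError("distance matrix contains non-finite values")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise OrdinationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise OrdinationError("distance matrix has a nonzero diagonal")
        self.values = v


@dataclass
class PCoAEmbedding:
    """Principal-coordinate embedding: coordinates scaled by sqrt(eigenvalue)."""

    sample_ids: list
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # descending, positive, one per retained axis


@dataclass
class PlaneModel:
    """A 2-D plane in 3-D principal-coordinate space: centroid + unit normal."""

    centroid: np.ndarray
    normal: np.ndarray
    group: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if self.centroid.shape != (3,) or self.normal.shape != (3,):
            raise PlaneFitError("centroid and normal must be 3-vectors")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-12:
            raise PlaneFitError("plane normal must have unit length")


@dataclass
class DistanceSeries:
    """Per-sample distances to the healthy and disease planes.

    ``data`` columns: sample_id (index), group, timepoint, dist_hp, dist_dp.
    ``planes`` maps (\"HP\"|\"DP\", timepoint) to the fitted :class:`PlaneModel`.
    """

    data: pd.DataFrame
    planes: dict = field(default_factory=dict)


@dataclass
class PairedTResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def bray_curtis(profile: AbundanceProfile) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(x, y) = sum|x-y| / sum(x+y).

    A pair of all-zero samples is defined to have distance 0.
    """
    x = profile.values
    if x.shape[0] < 2:
        raise OrdinationError("need at least two samples for a distance matrix")
    with np.errstate(invalid="ignore"):
        d = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(x, metric="braycurtis")
        )
    # 0/0 for two all-zero samples: identical communities, distance 0.
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(profile.sample_ids, d)


def pcoa(dist: DistanceMatrix, k: int = 3) -> PCoAEmbedding:
    """Classical scaling of a distance matrix (Gower double-centering).

    Eigendecomposes -0.5 * J D^2 J; axes with eigenvalue <= 1e-8 x the
    largest eigenvalue (including all negative axes) are dropped and
    coordinates are scaled by sqrt(eigenvalue).  If fewer than ``k``
    positive axes remain, ``k`` is reduced with a warning.
    """
    if k < 1:
        raise OrdinationError(f"k must be >= 1, got {k}")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = scipy.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = max(eigval[0], 0.0)
    keep = eigval > 1e-8 * top if top > 0 else np.zeros(n, dtype=bool)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    m = eigval.size
    if m < k:
        warnings.warn(
            f"only {m} positive principal coordinates available; k reduced from {k}",
            stacklevel=2,
        )
        k = m
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return PCoAEmbedding(list(dist.sample_ids), coords, eigval[:k].copy())


def fit_plane(points, group: str | None = None, timepoint: str | None = None) -> PlaneModel:
    """Orthogonal least-squares plane through a 3-D point cloud.

    Centroid is the mean point; the normal is the right singular vector of
    the centered cloud with smallest singular value (total least squares),
    sign-canonicalized so its first nonzero component is positive.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise PlaneFitError("points must be an (n, 3) array")
    if not np.isfinite(p).all():
        raise PlaneFitError("points contain non-finite values")
    if p.shape[0] < 3:
        raise PlaneFitError(f"need at least 3 points to fit a plane, got {p.shape[0]}")
    centroid = p.mean(axis=0)
    centered = p - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    if s[0] <= 0 or s[1] <= 1e-10 * s[0]:
        raise PlaneFitError("points are collinear or coincident; plane is undetermined")
    normal = vt[2]
    nz = np.flatnonzero(np.abs(normal) > 1e-12)
    if nz.size and normal[nz[0]] < 0:
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return PlaneModel(centroid, normal, group=group, timepoint=timepoint)


def distance_to_plane(point, plane: PlaneModel) -> float:
    """Euclidean (orthogonal) distance from a point to a plane."""
    p = np.asarray(point, dtype=float)
    if p.shape != (3,):
        raise OrdinationError("point must be a 3-vector")
    if not np.isfinite(p).all():
        raise OrdinationError("point contains non-finite values")
    return float(abs(np.dot(p - plane.centroid, plane.normal)))


def plane_distance_series(
    embedding: PCoAEmbedding,
    meta: SampleMetadata,
    healthy_group: str = "normal",
    disease_group: str = "model",
) -> DistanceSeries:
    """Fit HP/DP per time point and record every sample's distances to both.

    Planes are fitted on the first three coordinates of the (single, joint)
    embedding: the HP on the healthy group's samples and the DP on the
    disease group's samples at each time point.
    """
    if embedding.coordinates.shape[1] < 3:
        raise OrdinationError(
            "embedding must retain at least 3 principal coordinates for plane fitting"
        )
    coords = embedding.coordinates[:, :3]
    m = meta.aligned_to(embedding.sample_ids)
    groups = m["group"].to_numpy()
    tps = m["timepoint"].to_numpy()
    planes: dict = {}
    rows = []
    for tp in sorted(set(tps)):
        at_tp = tps == tp
        for label, grp in (("HP", healthy_group), ("DP", disease_group)):
            sel = at_tp & (groups == grp)
            if sel.sum() < 3:
                raise OrdinationError(
                    f"timepoint {tp}: only {int(sel.sum())} '{grp}' samples; "
                    "need >= 3 to fit a plane"
                )
            planes[(label, tp)] = fit_plane(coords[sel], group=grp, timepoint=tp)
        hp, dp = planes[("HP", tp)], planes[("DP", tp)]
        for i in np.flatnonzero(at_tp):
            rows.append(
                {
                    "sample_id": embedding.sample_ids[i],
                    "group": groups[i],
                    "timepoint": tp,
                    "dist_hp": distance_to_plane(coords[i], hp),
                    "dist_dp": distance_to_plane(coords[i], dp),
                }
            )
    data = pd.DataFrame(rows).sort_values(["timepoint", "sample_id"])
    data = data.set_index("sample_id")
    return DistanceSeries(data, planes)


def paired_t(hp_distances, dp_distances) -> PairedTResult:
    """Paired two-sided t test on HP-vs-DP distance differences.

    Degenerate inputs are reported rather than raised: all-zero differences
    give (t=0, p=1); zero-variance nonzero-mean differences give p=0 with
    the ``degenerate`` flag set.
    """
    a = np.asarray(hp_distances, dtype=float)
    b = np.asarray(dp_distances, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise OrdinationError("paired_t requires equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise OrdinationError(f"paired_t requires n >= 2, got {n}")
    diff = a - b
    if np.all(diff == 0):
        return PairedTResult(0.0, 1.0, n)
    if diff.std(ddof=1) == 0:
        t = np.inf if diff.mean() > 0 else -np.inf
        return PairedTResult(float(t), 0.0, n, degenerate=True)
    res = scipy.stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), float(res.pvalue), n)


def score_plane_correlation(
    series: DistanceSeries,
    meta: SampleMetadata,
    score_column: str = "arthritis_score",
    covariate_names: tuple = ("weight", "group"),
):
    """Semi-partial Spearman correlations of arthritis score with HP/DP distance.

    Covariates (body weight and dummy-coded group by default) are regressed
    out of the plane distance; returns the (score vs HP-distance, score vs
    DP-distance) result pair.
    """
    from .correlation import build_covariates, semipartial_spearman

    m = meta.aligned_to(series.data.index)
    if score_column not in m.columns:
        raise OrdinationError(f"metadata has no '{score_column}' column")
    y = m[score_column].to_numpy(dtype=float)
    covars, names = build_covariates(m, covariate_names)
    results = []
    for col in ("dist_hp", "dist_dp"):
        x = series.data[col].to_numpy(dtype=float)
        results.append(
            semipartial_spearman(
                x, y, covars, x_name=col, y_name=score_column, covariate_names=names
            )
        )
    return tuple(results)
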