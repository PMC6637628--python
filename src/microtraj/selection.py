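"""Repeated-CV consensus selection of arthritis-correlated species.

The selection procedure regresses clinical arthritis scores on the
log/z-score-normalized species profile with a non-negative elastic net,
resampled by five-fold cross-validation repeated ten times: every repeat
shuffles the samples into folds, the penalty for each fold is chosen by an
inner cross-validation on the training portion (100 log-spaced values from
lambda_max down four decades, CV-minimum rule), and one model is fitted per
(fold, repeat) on that training portion — 50 models in total.  Models with
fewer than five nonzero coefficients are discarded, and a species enters
the consensus set only when it carries a positive coefficient in more than
25 of the retained models (strictly more than half of the 50 fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enet import ElasticNetError, ElasticNetModel, enet_path_nn, fit_elastic_net_nn, lambda_grid
from .profiles import AbundanceProfile, NormalizedProfile, SampleMetadata, filter_prevalence, log_zscore

__all__ = [
    "SelectionResult",
    "repeated_cv_select",
    "select_arthritis_species",
    "selection_report",
]


@dataclass
class SelectionResult:
    """Outcome of repeated-CV consensus selection.

    ``models`` holds only the retained models (>= ``min_nonzero`` nonzero
    coefficients); ``total_models_fit`` counts every model fitted
    (folds x repeats).  ``inclusion_counts`` is indexed by species and
    counts retained models with a positive coefficient for that species.
    """

    models: list
    inclusion_counts: pd.Series
    selected_species: list
    total_models_fit: int
    min_nonzero: int
    consensus_threshold: int

    @property
    def n_retained(self) -> int:
        return len(self.models)

    def select_at(self, consensus_threshold: int) -> list:
        """Consensus set at a different threshold (counts are unchanged)."""
        keep = self.inclusion_counts[self.inclusion_counts > consensus_threshold]
        return sorted(keep.index)


def _as_matrix(X, species_ids=None):
    if isinstance(X, NormalizedProfile):
        return X.values, list(X.species_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if species_ids is None:
        species_ids = [f"feature_{j}" for j in range(X.shape[1])]
    return X, list(species_ids)


def _inner_cv_lambda(
    X, y, alpha, inner_folds, n_lambdas, lambda_decades, tol, rng
) -> float:
    """Penalty minimizing mean inner-CV squared error (largest lambda on ties)."""
    n = X.shape[0]
    lambdas = lambda_grid(X, y, alpha, n_lambdas=n_lambdas, decades=lambda_decades)
    perm = rng.permutation(n)
    folds = np.array_split(perm, inner_folds)
    errs = np.zeros((inner_folds, lambdas.size))
    for f, val_idx in enumerate(folds):
        train_idx = np.concatenate([folds[g] for g in range(inner_folds) if g != f])
        betas, intercepts = enet_path_nn(
            X[train_idx], y[train_idx], lambdas, alpha=alpha, tol=tol
        )
        preds = X[val_idx] @ betas.T + intercepts  # samples x lambdas
        errs[f] = ((preds - y[val_idx, None]) ** 2).mean(axis=0)
    mean_err = errs.mean(axis=0)
    return float(lambdas[int(np.argmin(mean_err))])


def repeated_cv_select(
    X,
    y,
    species_ids=None,
    folds: int = 5,
    repeats: int = 10,
    alpha: float = 0.5,
    min_nonzero: int = 5,
    consensus_threshold: int = 25,
    seed: int = 0,
    inner_folds: int = 5,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
    tol: float = 1e-7,
) -> SelectionResult:
    """Repeated cross-validated non-negative elastic net with consensus filter.

    Parameters mirror the selection procedure described in the module
    docstring; ``X`` may be a :class:`NormalizedProfile`, a DataFrame or an
    array of z-scored abundances and ``y`` the per-sample arthritis scores.
    All randomness (fold shuffles, inner CV splits) derives from ``seed``.
    """
    X, species_ids = _as_matrix(X, species_ids)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ElasticNetError("X and y have inconsistent sample counts")
    if folds < 2:
        raise ElasticNetError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ElasticNetError(f"folds={folds} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    models: list[ElasticNetModel] = []
    for r in range(repeats):
        perm = rng.permutation(n)
        fold_idx = np.array_split(perm, folds)
        for f in range(folds):
            train = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            lam = _inner_cv_lambda(
                X[train], y[train], alpha, inner_folds, n_lambdas, lambda_decades, tol, rng
            )
            model = fit_elastic_net_nn(
                X[train], y[train], lam, alpha=alpha, tol=tol, feature_names=species_ids
            )
            model.fold = f
            model.repeat = r
            models.append(model)
    total = len(models)
    retained = [m for m in models if m.n_nonzero >= min_nonzero]
    counts = np.zeros(len(species_ids), dtype=int)
    for m in retained:
        counts += (m.beta > 0).astype(int)
    inclusion = pd.Series(counts, index=species_ids, name="inclusion_count")
    selected = sorted(inclusion.index[inclusion > consensus_threshold])
    return SelectionResult(
        models=retained,
        inclusion_counts=inclusion,
        selected_species=selected,
        total_models_fit=total,
        min_nonzero=min_nonzero,
        consensus_threshold=consensus_threshold,
    )


def select_arthritis_species(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    score_column: str = "arthritis_score",
    min_prevalence: float = 0.05,
    **kwargs,
) -> SelectionResult:
    """End-to-end selection from a raw percent-scale profile.

    Applies the rat-prevalence filter and log/z-score normalization, then
    runs :func:`repeated_cv_select` against the arthritis scores.
    """
    filtered = filter_prevalence(profile, meta, min_fraction=min_prevalence)
    norm = log_zscore(filtered)
    y = meta.aligned_to(norm.sample_ids)[score_column].to_numpy(dtype=float)
    return repeated_cv_select(norm, y, **kwargs)


def selection_report(result: SelectionResult) -> pd.DataFrame:
    """Tabulate inclusion counts and coefficients for species seen in models.

    One row per species with a positive coefficient in at least one
    retained model: inclusion count, mean nonzero coefficient, association
    direction (always "+" under the nonnegativity constraint) and the
    consensus flag; sorted by count descending, ties broken
    lexicographically by species id.
    """
    counts = result.inclusion_counts
    species = [s for s in counts.index if counts[s] > 0]
    rows = []
    for s in species:
        j = counts.index.get_loc(s)
        nonzero = [m.beta[j] for m in result.models if m.beta[j] > 0]
        rows.append(
            {
                "species": s,
                "inclusion_count": int(counts[s]),
                "mean_nonzero_beta": float(np.mean(nonzero)) if nonzero else 0.0,
                "direction": "+",
                "selected": s in result.selected_species,
            }
        )
    report = pd.DataFrame(
        rows, columns=["species", "inclusion_count", "mean_nonzero_beta", "direction", "selected"]
    )
    if len(report):
        report = report.sort_values(
            ["inclusion_count", "species"], ascending=[False, True]
        ).reset_index(drop=True)
    return report
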