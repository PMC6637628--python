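"""Normal-referenced per-rat log10 fold changes and the consistency rule.

Abundances of (typically the consensus-selected) species in the disease and
treated groups are first normalized by the mean abundance of the untreated
healthy reference group at the same time point, then expressed per rat as
log10 fold changes of each later time point against the rat's own baseline
(TP1) sample.  A change is called significant for a (species, group, time
point) cell when strictly more than 80% of the group's rats show a greater
than 16-fold change (|log10 FC| > log10(16) ~ 1.20) *in the same
direction*.

A shared scale-aware pseudocount (half the smallest nonzero abundance in
the table) keeps all ratios finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AbundanceProfile, SampleMetadata, half_min_nonzero

__all__ = [
    "FoldChangeTable",
    "SignificanceCall",
    "FoldChangeError",
    "normalize_to_reference",
    "log10_fc_vs_baseline",
    "call_significant",
    "calls_table",
    "fold_threshold_log10",
]


class FoldChangeError(ValueError):
    """Invalid input to the fold-change machinery."""


def fold_threshold_log10(threshold_fold: float = 16.0) -> float:
    """The |log10 FC| cutoff equivalent to a given fold change (16 -> ~1.20)."""
    if threshold_fold <= 1:
        raise FoldChangeError(f"threshold_fold must be > 1, got {threshold_fold}")
    return math.log10(threshold_fold)


@dataclass
class FoldChangeTable:
    """Long-format per-rat fold changes vs the baseline time point.

    ``data`` columns: rat_id, group, species, timepoint, log10_fc; only
    non-baseline time points are present.
    """

    data: pd.DataFrame
    baseline: str


@dataclass
class SignificanceCall:
    """Outcome of the consistency rule for one (species, group, contrast)."""

    species: str
    group: str
    timepoint: str
    direction: int  # +1 / -1, 0 when no rat passes or signs conflict
    fraction_passing: float
    n_rats: int
    significant: bool


def normalize_to_reference(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    reference_group: str = "normal",
    eps: float | None = None,
    include_reference: bool = False,
    reference_statistic: str = "mean",
) -> pd.DataFrame:
    """Divide abundances by the reference-group mean at the same time point.

    ``value(sample, species) = (a + eps) / (mean_ref(a) + eps)`` with the
    reference mean taken over the reference group's samples at the sample's
    time point (``reference_statistic="median"`` substitutes the median).
    Returns a samples x species DataFrame covering the non-reference
    samples (all samples with ``include_reference``).
    """
    if reference_statistic not in ("mean", "median"):
        raise FoldChangeError(f"unknown reference statistic {reference_statistic!r}")
    meta.validate_against(profile)
    m = meta.aligned_to(profile.sample_ids)
    if eps is None:
        eps = half_min_nonzero(profile.values)
    groups = m["group"].to_numpy()
    tps = m["timepoint"].to_numpy()
    is_ref = groups == reference_group
    if not is_ref.any():
        raise FoldChangeError(f"reference group {reference_group!r} has no samples")
    out_mask = np.ones(len(groups), dtype=bool) if include_reference else ~is_ref
    needed_tps = sorted(set(tps[out_mask]))
    values = profile.values
    ref_stats = {}
    for tp in needed_tps:
        sel = is_ref & (tps == tp)
        if not sel.any():
            raise FoldChangeError(
                f"reference group {reference_group!r} has no samples at timepoint {tp}"
            )
        block = values[sel]
        ref_stats[tp] = block.mean(axis=0) if reference_statistic == "mean" else np.median(block, axis=0)
    normalized = np.empty((int(out_mask.sum()), values.shape[1]))
    out_rows = np.flatnonzero(out_mask)
    for k, i in enumerate(out_rows):
        normalized[k] = (values[i] + eps) / (ref_stats[tps[i]] + eps)
    return pd.DataFrame(
        normalized,
        index=[profile.sample_ids[i] for i in out_rows],
        columns=profile.species_ids,
    )


def log10_fc_vs_baseline(
    normalized: pd.DataFrame,
    meta: SampleMetadata,
    baseline: str = "TP1",
) -> FoldChangeTable:
    """Per-rat log10 fold change of each time point against the baseline.

    ``FC(rat, species, tp) = log10(norm(rat, species, tp) / norm(rat,
    species, baseline))``; every rat must have a baseline sample.
    """
    m = meta.aligned_to(normalized.index)
    rats = m["rat_id"].to_numpy()
    tps = m["timepoint"].to_numpy()
    groups = m["group"].to_numpy()
    if baseline not in set(tps):
        raise FoldChangeError(f"no samples at baseline timepoint {baseline!r}")
    base_row = {}
    for i, (rat, tp) in enumerate(zip(rats, tps)):
        if tp == baseline:
            base_row[rat] = i
    missing = sorted(set(rats) - set(base_row))
    if missing:
        raise FoldChangeError(f"rats missing a {baseline} baseline sample: {missing[:5]}")
    values = normalized.to_numpy(dtype=float)
    if (values <= 0).any():
        raise FoldChangeError("normalized values must be positive (pseudocount missing?)")
    frames = []
    species = list(normalized.columns)
    for i in range(len(rats)):
        if tps[i] == baseline:
            continue
        fc = np.log10(values[i] / values[base_row[rats[i]]])
        frames.append(
            pd.DataFrame(
                {
                    "rat_id": rats[i],
                    "group": groups[i],
                    "species": species,
                    "timepoint": tps[i],
                    "log10_fc": fc,
                }
            )
        )
    if not frames:
        data = pd.DataFrame(columns=["rat_id", "group", "species", "timepoint", "log10_fc"])
    else:
        data = pd.concat(frames, ignore_index=True)
    return FoldChangeTable(data, baseline)


def call_significant(
    fc: FoldChangeTable,
    threshold_fold: float = 16.0,
    rat_fraction: float = 0.8,
) -> list[SignificanceCall]:
    """Apply the consistency rule per (species, group, time point).

    A rat passes when |log10 FC| strictly exceeds log10(threshold_fold);
    the cell is significant when the passing fraction strictly exceeds
    ``rat_fraction`` and all passing rats share one sign (which becomes the
    call's direction).
    """
    if not 0.0 <= rat_fraction < 1.0:
        raise FoldChangeError(f"rat_fraction must be in [0, 1), got {rat_fraction}")
    cut = fold_threshold_log10(threshold_fold)
    calls = []
    for (species, group, tp), sub in fc.data.groupby(
        ["species", "group", "timepoint"], sort=True
    ):
        vals = sub["log10_fc"].to_numpy(dtype=float)
        n = vals.size
        passing = np.abs(vals) > cut
        frac = float(passing.mean()) if n else 0.0
        signs = np.sign(vals[passing])
        consistent = passing.any() and (np.all(signs > 0) or np.all(signs < 0))
        significant = bool(consistent and frac > rat_fraction)
        direction = int(signs[0]) if consistent else 0
        calls.append(
            SignificanceCall(
                species=species,
                group=group,
                timepoint=tp,
                direction=direction,
                fraction_passing=frac,
                n_rats=n,
                significant=significant,
            )
        )
    return calls


def calls_table(calls: list[SignificanceCall]) -> pd.DataFrame:
    """Significance calls as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "group": c.group,
                "timepoint": c.timepoint,
                "direction": c.direction,
                "fraction_passing": c.fraction_passing,
                "n_rats": c.n_rats,
                "significant": c.significant,
            }
            for c in calls
        ],
        columns=[
            "species",
            "group",
            "timepoint",
            "direction",
            "fraction_passing",
            "n_rats",
            "significant",
        ],
    )
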