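"""KEGG ortholog (KO) and module-level differential statistics.

KO relative abundances are aggregated to KEGG modules (mean over member
KOs by default), individual KOs are compared between groups at the final
sampling day with the Wilcoxon rank-sum W statistic, and each module's
shift over the study is summarized as the log2 fold change of its mean
abundance at the last time point versus baseline, computed per group.

The pipeline consumes a precomputed KO table and a module->KO membership
map; KEGG database construction and protein alignment are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .profiles import SampleMetadata, half_min_nonzero, _check_unique

__all__ = [
    "KOProfile",
    "ModuleMap",
    "TestResult",
    "KeggError",
    "read_ko_profile",
    "write_ko_profile",
    "read_module_map",
    "write_module_map",
    "module_abundance",
    "wilcoxon_rank_sum",
    "ko_differential",
    "module_log2fc",
]


class KeggError(ValueError):
    """Invalid input to the KEGG machinery."""


@dataclass
class KOProfile:
    """Samples x KO relative abundances (nonnegative, unique axes)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids", KeggError)
        _check_unique(self.data.columns, "KO ids", KeggError)
        v = self.data.to_numpy(dtype=float)
        if v.size and not np.isfinite(v).all():
            raise KeggError("KO profile contains non-finite values")
        if v.size and (v < 0).any():
            raise KeggError("KO profile contains negative abundances")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def ko_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ModuleMap:
    """Module id -> member KO ids, with optional free-text annotations."""

    members: dict
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise KeggError("module map is empty")
        for mod, kos in self.members.items():
            if not kos:
                raise KeggError(f"module {mod!r} has no member KOs")
            self.members[mod] = tuple(kos)


@dataclass
class TestResult:
    """Wilcoxon rank-sum outcome for one KO or module."""

    unit: str | None
    w: float  # rank sum of the first group
    p_value: float
    direction: int  # sign of (mean rank a - mean rank b)
    n_a: int
    n_b: int
    method: str  # "exact" or "normal"


def read_ko_profile(path) -> KOProfile:
    """Read a KO table: first column ``ko_id``, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KOProfile(df.T.astype(float))


def write_ko_profile(profile: KOProfile, path) -> None:
    out = profile.data.T
    out.index.name = "ko_id"
    out.to_csv(path, sep="\t")


def read_module_map(path) -> ModuleMap:
    """Read a module map TSV: module_id, ko_id[, annotation] per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"module_id", "ko_id"}
    if not required.issubset(df.columns):
        raise KeggError(f"{path}: module map needs columns {sorted(required)}")
    members: dict = {}
    annotations: dict = {}
    for _, row in df.iterrows():
        members.setdefault(row["module_id"], []).append(row["ko_id"])
        if "annotation" in df.columns and pd.notna(row.get("annotation")):
            annotations[row["module_id"]] = row["annotation"]
    return ModuleMap(members, annotations)


def write_module_map(mmap: ModuleMap, path) -> None:
    rows = [
        {"module_id": mod, "ko_id": ko, "annotation": mmap.annotations.get(mod, "")}
        for mod, kos in mmap.members.items()
        for ko in kos
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def module_abundance(
    ko: KOProfile, mmap: ModuleMap, agg: str = "mean"
) -> pd.DataFrame:
    """Aggregate KO abundances to modules (samples x modules).

    Module abundance is the mean (or, with ``agg="sum"``, the sum) over the
    member KOs present in the profile; modules with no present member are
    dropped with a warning.
    """
    if agg not in ("mean", "sum"):
        raise KeggError(f"unknown aggregation {agg!r}")
    present = set(ko.data.columns)
    cols = {}
    dropped = []
    for mod, kos in mmap.members.items():
        member = [k for k in kos if k in present]
        if not member:
            dropped.append(mod)
            continue
        block = ko.data.loc[:, member]
        cols[mod] = block.mean(axis=1) if agg == "mean" else block.sum(axis=1)
    if dropped:
        warnings.warn(
            f"{len(dropped)} module(s) with no KO present in the profile dropped: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    if not cols:
        raise KeggError("no module has any member KO present in the profile")
    return pd.DataFrame(cols, index=ko.data.index)


def wilcoxon_rank_sum(a, b, unit: str | None = None) -> TestResult:
    """Two-sample Wilcoxon rank-sum test reporting the classic W statistic.

    W is the sum of pooled ranks of the first group (average ranks on
    ties).  The two-sided p-value is exact (full enumeration) when
    n1 + n2 <= 12 and the pooled values are tie-free, otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise KeggError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise KeggError("non-finite values in test input")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_diff = ranks[:n1].mean() - ranks[n1:].mean()
    direction = int(np.sign(mean_diff))
    ties = np.unique(pooled).size < pooled.size
    exact = (n1 + n2 <= 12) and not ties
    res = scipy.stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        unit=unit,
        w=w,
        p_value=float(res.pvalue),
        direction=direction,
        n_a=n1,
        n_b=n2,
        method="exact" if exact else "normal",
    )


def ko_differential(
    ko: KOProfile,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    timepoint: str = "TP5",
) -> pd.DataFrame:
    """Per-KO rank-sum tests between two groups at one time point."""
    m = meta.aligned_to(ko.sample_ids)
    sel_a = (m["group"] == group_a) & (m["timepoint"] == timepoint)
    sel_b = (m["group"] == group_b) & (m["timepoint"] == timepoint)
    if not sel_a.any() or not sel_b.any():
        raise KeggError(
            f"no samples for group(s) {group_a!r}/{group_b!r} at timepoint {timepoint!r}"
        )
    va = ko.values[sel_a.to_numpy()]
    vb = ko.values[sel_b.to_numpy()]
    rows = []
    for j, ko_id in enumerate(ko.ko_ids):
        r = wilcoxon_rank_sum(va[:, j], vb[:, j], unit=ko_id)
        rows.append(
            {
                "unit": ko_id,
                "w": r.w,
                "p_value": r.p_value,
                "direction": r.direction,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows).set_index("unit")


def module_log2fc(
    modules: pd.DataFrame,
    meta: SampleMetadata,
    tp_num: str = "TP5",
    tp_den: str = "TP1",
    groups=None,
    eps: float | None = None,
    require_all_groups: bool = False,
) -> pd.DataFrame:
    """Per-group log2 fold change of module means, final vs baseline TP.

    ``log2((mean at tp_num + eps) / (mean at tp_den + eps))`` per module
    and group.  A module absent from a group (zero mean at both time
    points) is reported as NaN there; ``require_all_groups`` drops such
    rows entirely, mirroring an all-groups-present report filter.
    """
    m = meta.aligned_to(modules.index)
    tps = set(m["timepoint"])
    for tp in (tp_num, tp_den):
        if tp not in tps:
            raise KeggError(f"unknown contrast timepoint {tp!r}")
    if groups is None:
        groups = list(dict.fromkeys(m["group"]))
    if eps is None:
        eps = half_min_nonzero(modules.to_numpy())
    out = {}
    for g in groups:
        sel_num = (m["group"] == g) & (m["timepoint"] == tp_num)
        sel_den = (m["group"] == g) & (m["timepoint"] == tp_den)
        if not sel_num.any() or not sel_den.any():
            raise KeggError(f"group {g!r} lacks samples at {tp_num!r} or {tp_den!r}")
        mean_num = modules.loc[sel_num.to_numpy()].mean(axis=0)
        mean_den = modules.loc[sel_den.to_numpy()].mean(axis=0)
        fc = np.log2((mean_num + eps) / (mean_den + eps))
        fc[(mean_num == 0) & (mean_den == 0)] = np.nan
        out[g] = fc
    table = pd.DataFrame(out)
    if require_all_groups:
        table = table.dropna(axis=0, how="any")
    return table
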