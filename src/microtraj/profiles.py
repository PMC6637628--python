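"""Species-level profile and sample-metadata tables.

This module houses the two tables that every downstream stage shares: a
compositional species profile (samples x species, relative abundance on the
profiler's native percent scale) and the per-sample metadata record (rat,
group, time point, body weight, arthritis score, serum cytokines).  It also
implements the two preprocessing steps applied before regression-based
species selection:

* a prevalence filter that drops species observed in fewer than a given
  fraction of *rats* (a rat "presents" a species if the abundance is
  positive in at least one of its longitudinal samples), and
* a log10 / z-score normalization with a scale-aware pseudocount (half the
  smallest nonzero value of the table) and population-variance scaling.

On-disk format is the MetaPhlAn-style TSV dialect: first column
``clade_name``, one column per sample, species rows identified by an
``s__`` clade element without a trailing ``t__`` (strain) element.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CYTOKINES",
    "AbundanceProfile",
    "SampleMetadata",
    "NormalizedProfile",
    "ProfileError",
    "MetadataError",
    "half_min_nonzero",
    "is_species_clade",
    "read_profile",
    "write_profile",
    "read_metadata",
    "write_metadata",
    "filter_prevalence",
    "log_zscore",
]

#: Serum cytokine column names used throughout (concentrations, pg/mL).
CYTOKINES = ("il17", "il1b", "tnfa", "il6", "ifng", "il2")

#: Metadata columns required for the full pipeline.
REQUIRED_METADATA_COLUMNS = ("rat_id", "group", "timepoint")


class ProfileError(ValueError):
    """Malformed or inconsistent abundance profile."""


class MetadataError(ValueError):
    """Malformed or inconsistent sample metadata."""


def half_min_nonzero(values) -> float:
    """Scale-aware pseudocount: half the smallest nonzero entry of a table.

    Falls back to 1e-6 when the table contains no positive entry (the value
    is then immaterial; it only keeps logarithms finite).
    """
    v = np.asarray(values, dtype=float)
    nz = v[v > 0]
    if nz.size == 0:
        return 1e-6
    return float(nz.min()) / 2.0


def is_species_clade(name: str) -> bool:
    """True for clade names that terminate at species level (``s__`` present,
    no strain-level ``t__`` element)."""
    return "s__" in name and "t__" not in name


def _check_unique(ids, what: str, err):
    dup = [k for k, c in Counter(ids).items() if c > 1]
    if dup:
        raise err(f"duplicate {what}: {sorted(dup)[:5]}")


@dataclass
class AbundanceProfile:
    """Samples x species relative abundances on the percent scale.

    ``data`` is indexed by sample id with species clade names as columns.
    Values are nonnegative and each sample sums to at most 100 (compositional
    profiles may sum to less when unclassified mass is excluded).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids", ProfileError)
        _check_unique(self.data.columns, "species ids", ProfileError)
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ProfileError("profile contains non-finite values")
        if values.size and (values < 0).any():
            raise ProfileError("profile contains negative abundances")
        if values.size:
            sums = values.sum(axis=1)
            bad = np.flatnonzero(sums > 100.0 + 1e-6)
            if bad.size:
                raise ProfileError(
                    f"sample(s) {list(self.data.index[bad][:5])} sum to more than 100%"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_species(self, species) -> "AbundanceProfile":
        missing = [s for s in species if s not in self.data.columns]
        if missing:
            raise ProfileError(f"species not in profile: {missing[:5]}")
        return AbundanceProfile(self.data.loc[:, list(species)].copy())


@dataclass
class NormalizedProfile:
    """Samples x species z-scores of log10 abundance (see :func:`log_zscore`)."""

    data: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample study metadata, indexed by sample id.

    Required columns: ``rat_id``, ``group``, ``timepoint``.  The full design
    additionally carries ``weight`` (g), ``arthritis_score`` and the serum
    cytokines in :data:`CYTOKINES` (pg/mL).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise MetadataError(f"metadata is missing required columns: {missing}")
        _check_unique(df.index, "sample ids", MetadataError)
        pairs = list(zip(df["rat_id"], df["timepoint"]))
        _check_unique(pairs, "(rat_id, timepoint) pairs", MetadataError)
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.data["group"]))

    @property
    def timepoints(self) -> list:
        """Timepoint labels in sorted order (TP1..TP5 sorts naturally)."""
        return sorted(set(self.data["timepoint"]))

    def validate_against(self, profile: AbundanceProfile) -> None:
        missing = [s for s in profile.sample_ids if s not in self.data.index]
        if missing:
            raise MetadataError(
                f"profile samples without a metadata row: {missing[:5]}"
            )

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise MetadataError(f"samples without metadata: {missing[:5]}")
        return self.data.loc[list(sample_ids)]


# ---------------------------------------------------------------------------
# I/O


def read_profile(path, species_only: bool = True) -> AbundanceProfile:
    """Read a MetaPhlAn-style TSV profile (clade rows, sample columns).

    Only rows whose clade name terminates at species level are retained when
    ``species_only`` is set.  Raises :class:`ProfileError` with row/column
    context on malformed input.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.strip() == "":
        raise ProfileError(f"{path}: empty file")
    header = first.rstrip("\n").split("\t")
    if len(header) < 2:
        raise ProfileError(
            f"{path}: header must contain a clade-name column plus at least one sample column"
        )
    _check_unique(header[1:], f"sample columns in {path}", ProfileError)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ProfileError(f"{path}: no data rows")
    parsed = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ProfileError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        parsed[col] = numeric
    table = pd.DataFrame(parsed, index=df.index)
    if species_only:
        keep = [c for c in table.index if is_species_clade(str(c))]
        table = table.loc[keep]
    return AbundanceProfile(table.T)


def write_profile(profile: AbundanceProfile, path) -> None:
    """Write a profile in the same TSV dialect :func:`read_profile` reads."""
    out = profile.data.T
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "rat_id": str})
    if "sample_id" not in df.columns:
        raise MetadataError(f"{path}: missing 'sample_id' column")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Preprocessing


def filter_prevalence(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    min_fraction: float = 0.05,
) -> AbundanceProfile:
    """Drop species presenting in fewer than ``min_fraction`` of rats.

    A rat presents a species if its abundance is positive in at least one of
    the rat's samples; a species is kept iff the presenting-rat fraction is
    >= ``min_fraction``.  The sample axis is unchanged.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ProfileError(f"min_fraction must be in [0, 1], got {min_fraction}")
    meta.validate_against(profile)
    rats = meta.aligned_to(profile.sample_ids)["rat_id"].to_numpy()
    present = profile.data > 0
    per_rat = present.groupby(rats).any()
    frac = per_rat.mean(axis=0)
    keep = frac[frac >= min_fraction].index
    return AbundanceProfile(profile.data.loc[:, keep].copy())


def log_zscore(profile: AbundanceProfile, eps: float | None = None) -> NormalizedProfile:
    """Log10-transform then z-score each species across samples.

    ``v' = log10(v + eps)`` with ``eps`` defaulting to half the smallest
    nonzero value of the table, followed by per-species centering and
    scaling by the population (n-denominator) standard deviation.
    Zero-variance species map to all-zero columns.
    """
    values = profile.values
    if values.size == 0:
        raise ProfileError("cannot normalize an empty profile")
    if eps is None:
        eps = half_min_nonzero(values)
    logged = np.log10(values + eps)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)  # population SD, ddof=0
    # constant columns: the mean of identical floats can round a last-place
    # unit away from them, so test the value range rather than sd alone
    constant = (np.ptp(logged, axis=0) == 0) | (sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[:, constant] = 0.0
    return NormalizedProfile(
        pd.DataFrame(z, index=profile.data.index, columns=profile.data.columns)
    )
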