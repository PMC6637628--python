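"""Synthetic longitudinal arthritis-cohort generator with known ground truth.

Emulates the study design every downstream stage expects: four groups
(untreated healthy controls, the untreated disease model, and two treated
arms) of seven rats each, sampled at five time points.  Species profiles
are generated on the log10 scale (log-normal per species) and closed to
100% per sample.  A designated subset of species drifts linearly in log
abundance across time in the disease model — the "dysbiosis" — while
treated groups experience only a configurable fraction of that drift
(partial reversion).  A small planted subset of the drifting species
linearly drives the clinical arthritis score, selected serum cytokines are
coupled multiplicatively to specific species, and a KO table carries
planted module-level shifts.  Everything is reproducible bit-for-bit from
a single seed, split into independent streams per output table.

The generator does not attempt to mimic sequencing reads, profiler error
or host contamination; it produces the profile tables the pipeline starts
from.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .kegg import KOProfile, ModuleMap
from .profiles import CYTOKINES, AbundanceProfile, SampleMetadata

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CytokineCoupling",
    "KoShift",
    "SimConfigError",
    "simulate_cohort",
    "simulate_ko_shifts",
    "default_module_map",
    "save_config",
    "load_config",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration (the message names the field)."""


@dataclass(frozen=True)
class CytokineCoupling:
    """Multiplicative coupling of one cytokine to one species' z-abundance."""

    species: str
    cytokine: str
    sign: int
    strength: float


@dataclass(frozen=True)
class KoShift:
    """A planted multiplicative shift of one module in one group/time point."""

    module: str
    group: str
    timepoint: str
    factor: float


#: Baseline serum concentrations (pg/mL) used when none are configured.
DEFAULT_CYTOKINE_BASELINES = {
    "il17": 50.0,
    "il1b": 40.0,
    "tnfa": 30.0,
    "il6": 60.0,
    "ifng": 25.0,
    "il2": 20.0,
}


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Group semantics follow position: the first group is the untreated
    healthy reference (no dysbiosis drift, arthritis score pinned at 0 as
    unimmunized controls), the second is the untreated disease model (full
    drift), and any further groups are treated arms whose drift is scaled
    by ``1 - reversion_fraction``.

    Magnitudes are on the scales the pipeline sees: ``drift_magnitude``
    and ``noise_sd`` are log10 abundance units, ``signal_effect`` is
    arthritis-score units per z-unit of a planted species' log abundance,
    cytokine strengths are natural-log units per z-unit.
    """

    n_rats_per_group: int = 7
    groups: tuple = ("normal", "model", "mtx", "lcasei")
    timepoints: tuple = ("TP1", "TP2", "TP3", "TP4", "TP5")
    n_species: int = 200
    n_signal_species: int = 5
    n_drift_species: int = 40
    signal_effect: float = 1.0
    drift_magnitude: float = 2.0
    severity_sd: float = 0.1
    response_sd: float = 0.55
    reversion_fraction: float = 0.7
    noise_sd: float = 0.5
    baseline_log_abundance_sd: float = 1.2
    baseline_score: float = 0.0
    score_noise_sd: float = 0.5
    max_score: float = 16.0
    cytokine_baselines: dict = field(
        default_factory=lambda: dict(DEFAULT_CYTOKINE_BASELINES)
    )
    cytokine_noise_sd: float = 0.25
    cytokine_couplings: tuple | None = None  # None -> defaults on signal species
    n_modules: int = 30
    kos_per_module: int = 5
    n_background_kos: int = 50
    ko_noise_sd: float = 0.2
    ko_shifts: tuple | None = None  # None -> default planted shifts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_rats_per_group",
            "n_species",
            "n_signal_species",
            "n_modules",
            "kos_per_module",
        ):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be a positive integer")
        for name in ("n_drift_species", "n_background_kos"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if len(self.groups) < 2:
            raise SimConfigError("groups must list at least a healthy and a disease group")
        if len(set(self.groups)) != len(self.groups):
            raise SimConfigError("groups must be unique labels")
        if len(self.timepoints) < 2:
            raise SimConfigError("timepoints must list at least two labels")
        if self.n_signal_species > self.n_species:
            raise SimConfigError("n_signal_species must not exceed n_species")
        if self.n_drift_species > self.n_species:
            raise SimConfigError("n_drift_species must not exceed n_species")
        if self.n_signal_species > max(self.n_drift_species, 1):
            raise SimConfigError("n_signal_species must not exceed n_drift_species")
        if not 0.0 <= self.reversion_fraction <= 1.0:
            raise SimConfigError("reversion_fraction must be in [0, 1]")
        for name in (
            "noise_sd",
            "score_noise_sd",
            "cytokine_noise_sd",
            "ko_noise_sd",
            "baseline_log_abundance_sd",
            "severity_sd",
            "response_sd",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.max_score <= 0:
            raise SimConfigError("max_score must be > 0")
        unknown = {
            c for c in self.cytokine_baselines if c not in CYTOKINES
        }
        if unknown:
            raise SimConfigError(f"cytokine_baselines names unknown cytokines: {sorted(unknown)}")

    @classmethod
    def planted_signal(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Recovery-test scenario: drift confined to the planted species.

        The five signal species carry a clean linear association with the
        arthritis score while the remaining species are exchangeable noise,
        so a false selection is unambiguously a false positive.  (In the
        default full-drift cohort the co-drifting species are genuinely
        disease-associated, which makes that notion ill-defined.)
        """
        params = {"n_drift_species": None, "seed": seed, **overrides}
        if params["n_drift_species"] is None:
            params["n_drift_species"] = overrides.get(
                "n_signal_species", cls.n_signal_species
            )
        return cls(**params)

    @property
    def healthy_group(self) -> str:
        return self.groups[0]

    @property
    def disease_group(self) -> str:
        return self.groups[1]

    @property
    def treated_groups(self) -> tuple:
        return tuple(self.groups[2:])


@dataclass
class GroundTruth:
    """What was planted, for recovery tests downstream."""

    signal_species: tuple
    score_weights: dict  # species -> score units per z-unit
    drift_directions: dict  # drifting species -> +1 / -1 (log10 direction)
    cytokine_couplings: tuple
    ko_shifts: tuple
    module_map: ModuleMap


def _species_names(n: int) -> list:
    return [
        f"k__Bacteria|p__P{i % 6}|g__G{i // 4:03d}|s__Species_{i:04d}" for i in range(n)
    ]


def _sample_grid(config: SimConfig):
    """Sample/rat/group/timepoint bookkeeping shared by all tables."""
    rows = []
    for g in config.groups:
        for r in range(1, config.n_rats_per_group + 1):
            rat = f"{g}_r{r:02d}"
            for t_idx, tp in enumerate(config.timepoints):
                rows.append(
                    {
                        "sample_id": f"{rat}_{tp}",
                        "rat_id": rat,
                        "group": g,
                        "timepoint": tp,
                        "t_idx": t_idx,
                    }
                )
    return pd.DataFrame(rows)


def _group_drift_factor(config: SimConfig, group: str) -> float:
    if group == config.healthy_group:
        return 0.0
    if group == config.disease_group:
        return 1.0
    return 1.0 - config.reversion_fraction


def default_module_map(
    n_modules: int = 30, kos_per_module: int = 5, n_background_kos: int = 50
) -> ModuleMap:
    """Deterministic synthetic module map (M0001.. with disjoint KO sets)."""
    members = {}
    ko_counter = 1
    for m in range(1, n_modules + 1):
        kos = [f"K{ko_counter + j:05d}" for j in range(kos_per_module)]
        ko_counter += kos_per_module
        members[f"M{m:04d}"] = tuple(kos)
    annotations = {mod: f"synthetic module {mod}" for mod in members}
    return ModuleMap(members, annotations)


def _default_ko_shifts(config: SimConfig, mmap: ModuleMap) -> tuple:
    modules = sorted(mmap.members)
    shifts = [KoShift(modules[0], config.disease_group, config.timepoints[-1], 4.0)]
    if len(modules) > 1:
        shifts.append(
            KoShift(modules[1], config.disease_group, config.timepoints[-1], 0.25)
        )
    return tuple(shifts)


def _ko_rng(config: SimConfig) -> np.random.Generator:
    # stream index 4 of the shared split; simulate_cohort uses the same one
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])


def simulate_ko_shifts(
    config: SimConfig, module_map: ModuleMap | None = None
) -> KOProfile:
    """KO table with planted multiplicative module shifts, rows closed to 100.

    Baseline log10 KO abundances are log-normal per KO with per-sample
    noise ``ko_noise_sd``; each configured shift multiplies the member KOs
    of one module in one (group, time point) cell before closure.  Called
    with the same config, this reproduces the KO table of
    :func:`simulate_cohort` exactly.
    """
    if module_map is None:
        module_map = default_module_map(
            config.n_modules, config.kos_per_module, config.n_background_kos
        )
    shifts = config.ko_shifts
    if shifts is None:
        shifts = _default_ko_shifts(config, module_map)
    shifts = tuple(
        s if isinstance(s, KoShift) else KoShift(**s) for s in shifts
    )
    for s in shifts:
        if s.module not in module_map.members:
            raise SimConfigError(
                f"ko_shifts references unknown module {s.module!r}"
            )
        if s.group not in config.groups:
            raise SimConfigError(f"ko_shifts references unknown group {s.group!r}")
        if s.timepoint not in config.timepoints:
            raise SimConfigError(
                f"ko_shifts references unknown timepoint {s.timepoint!r}"
            )
        if s.factor <= 0:
            raise SimConfigError("ko_shifts factors must be > 0")
    member_kos = [k for kos in module_map.members.values() for k in kos]
    background = [f"KB{j:05d}" for j in range(config.n_background_kos)]
    ko_ids = member_kos + background
    grid = _sample_grid(config)
    rng = _ko_rng(config)
    mu = rng.normal(0.0, 1.0, size=len(ko_ids))
    noise = rng.normal(0.0, config.ko_noise_sd, size=(len(grid), len(ko_ids)))
    log_abund = mu[None, :] + noise
    ko_pos = {k: j for j, k in enumerate(ko_ids)}
    for s in shifts:
        rows = ((grid["group"] == s.group) & (grid["timepoint"] == s.timepoint)).to_numpy()
        cols = [ko_pos[k] for k in module_map.members[s.module]]
        log_abund[np.ix_(rows, cols)] += np.log10(s.factor)
    abund = 10.0**log_abund
    abund = 100.0 * abund / abund.sum(axis=1, keepdims=True)
    return KOProfile(pd.DataFrame(abund, index=grid["sample_id"].tolist(), columns=ko_ids))


def simulate_cohort(config: SimConfig):
    """Generate (AbundanceProfile, SampleMetadata, KOProfile, GroundTruth).

    See the module docstring for the generative model.  One sample per rat
    per time point; species abundances are nonnegative and sum to 100 per
    sample; identical config + seed reproduces identical tables.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_comm, rng_score, rng_cyto, rng_weight, _ = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    species = _species_names(config.n_species)
    grid = _sample_grid(config)
    n_samples = len(grid)
    n_tp = len(config.timepoints)

    # --- community: baseline + drift + noise on the log10 scale -----------
    mu = rng_comm.normal(0.0, config.baseline_log_abundance_sd, size=config.n_species)
    drift_idx = rng_comm.choice(
        config.n_species, size=config.n_drift_species, replace=False
    )
    signal_idx = drift_idx[: config.n_signal_species]
    directions = np.zeros(config.n_species)
    # planted score-driving species drift upward in disease so that the
    # non-negative regression downstream can recover them; the remaining
    # drifters split randomly between enriched and depleted
    directions[signal_idx] = 1.0
    other = drift_idx[config.n_signal_species :]
    directions[other] = rng_comm.choice([-1.0, 1.0], size=other.size)
    # disease-enriched species bloom from rarity toward typical levels
    # (pathobiont expansion) while disease-depleted species start abundant
    # (commensal collapse); both keep the compositional closure shift small
    # enough that planted fold changes survive renormalization, and the
    # depletion of dominant taxa carries the community-scale distance signal
    mu = mu - config.drift_magnitude * (directions > 0) + 1.0 * (directions < 0)
    noise = rng_comm.normal(0.0, config.noise_sd, size=(n_samples, config.n_species))

    t_frac = grid["t_idx"].to_numpy() / (n_tp - 1)
    group_factor = grid["group"].map(
        {g: _group_drift_factor(config, g) for g in config.groups}
    ).to_numpy()
    # per-rat drift multipliers: untreated disease progresses consistently
    # (severity_sd, small) while treatment response varies across animals
    # (response_sd, larger); both scale the whole-community drift and hence,
    # through the planted species, the arthritis score
    rats = list(dict.fromkeys(grid["rat_id"]))
    rat_group = dict(zip(grid["rat_id"], grid["group"]))
    severity = {}
    for rat in rats:
        g = rat_group[rat]
        if g == config.healthy_group:
            severity[rat] = 1.0
        elif g == config.disease_group:
            severity[rat] = float(np.exp(rng_comm.normal(0.0, config.severity_sd)))
        else:
            severity[rat] = float(np.exp(rng_comm.normal(0.0, config.response_sd)))
    sev = grid["rat_id"].map(severity).to_numpy()
    drift_term = np.outer(
        t_frac * group_factor * sev, directions * config.drift_magnitude
    )
    log_abund = mu[None, :] + drift_term + noise
    abund = 10.0**log_abund
    abund = 100.0 * abund / abund.sum(axis=1, keepdims=True)
    profile = AbundanceProfile(
        pd.DataFrame(abund, index=grid["sample_id"].tolist(), columns=species)
    )

    # latent z-scores of log abundance (what the score and cytokines see)
    sd = log_abund.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_lat = (log_abund - log_abund.mean(axis=0)) / sd
    z_lat[:, sd == 0] = 0.0

    # --- arthritis score: linear in the planted species' z-abundance ------
    signal_names = tuple(species[i] for i in signal_idx)
    weights = {name: config.signal_effect for name in signal_names}
    score_noise = rng_score.normal(0.0, config.score_noise_sd, size=n_samples)
    raw = (
        config.baseline_score
        + z_lat[:, signal_idx] @ np.full(signal_idx.size, config.signal_effect)
        + score_noise
    )
    score = np.clip(raw, 0.0, config.max_score)
    score[(grid["group"] == config.healthy_group).to_numpy()] = 0.0

    # --- body weight: growth minus a disease penalty ----------------------
    weight = (
        60.0
        + 25.0 * grid["t_idx"].to_numpy()
        - 1.5 * score
        + rng_weight.normal(0.0, 2.0, size=n_samples)
    )

    # --- cytokines: multiplicative coupling to specific species -----------
    couplings = config.cytokine_couplings
    if couplings is None:
        defaults = [("il17", 1, 0.8), ("il6", 1, 0.8), ("tnfa", 1, 0.8), ("il2", -1, 0.6)]
        couplings = tuple(
            CytokineCoupling(signal_names[i % len(signal_names)], cyt, sgn, strength)
            for i, (cyt, sgn, strength) in enumerate(defaults[: max(1, len(signal_names))])
        )
    couplings = tuple(
        c if isinstance(c, CytokineCoupling) else CytokineCoupling(**c) for c in couplings
    )
    species_pos = {s: j for j, s in enumerate(species)}
    for c in couplings:
        if c.species not in species_pos:
            raise SimConfigError(f"cytokine_couplings references unknown species {c.species!r}")
        if c.cytokine not in CYTOKINES:
            raise SimConfigError(f"cytokine_couplings references unknown cytokine {c.cytokine!r}")
    cyto_noise = rng_cyto.normal(
        0.0, config.cytokine_noise_sd, size=(n_samples, len(CYTOKINES))
    )
    log_cyto = np.array(
        [np.log(config.cytokine_baselines.get(c, DEFAULT_CYTOKINE_BASELINES[c])) for c in CYTOKINES]
    )[None, :] + cyto_noise
    cyto_pos = {c: j for j, c in enumerate(CYTOKINES)}
    for c in couplings:
        log_cyto[:, cyto_pos[c.cytokine]] += (
            c.sign * c.strength * z_lat[:, species_pos[c.species]]
        )
    cyto = np.exp(log_cyto)

    meta_df = grid.drop(columns=["t_idx"]).copy()
    meta_df["weight"] = weight
    meta_df["arthritis_score"] = score
    for c in CYTOKINES:
        meta_df[c] = cyto[:, cyto_pos[c]]
    meta = SampleMetadata(meta_df)

    # --- KO table ---------------------------------------------------------
    module_map = default_module_map(
        config.n_modules, config.kos_per_module, config.n_background_kos
    )
    ko_profile = simulate_ko_shifts(config, module_map)
    ko_shifts = config.ko_shifts
    if ko_shifts is None:
        ko_shifts = _default_ko_shifts(config, module_map)
    ko_shifts = tuple(s if isinstance(s, KoShift) else KoShift(**s) for s in ko_shifts)

    truth = GroundTruth(
        signal_species=signal_names,
        score_weights=weights,
        drift_directions={
            species[i]: float(directions[i]) for i in drift_idx
        },
        cytokine_couplings=couplings,
        ko_shifts=ko_shifts,
        module_map=module_map,
    )
    return profile, meta, ko_profile, truth


# ---------------------------------------------------------------------------
# Config serialization (YAML)


def save_config(config: SimConfig, path) -> None:
    """Write a config as a YAML document (tuples become lists)."""
    raw = asdict(config)
    if raw["cytokine_couplings"] is not None:
        raw["cytokine_couplings"] = [asdict(c) if isinstance(c, CytokineCoupling) else dict(c) for c in config.cytokine_couplings]
    if raw["ko_shifts"] is not None:
        raw["ko_shifts"] = [asdict(s) if isinstance(s, KoShift) else dict(s) for s in config.ko_shifts]
    raw["groups"] = list(config.groups)
    raw["timepoints"] = list(config.timepoints)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_config(path) -> SimConfig:
    """Read a YAML config written by :func:`save_config`."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw.get("cytokine_couplings") is not None:
        raw["cytokine_couplings"] = tuple(
            CytokineCoupling(**c) for c in raw["cytokine_couplings"]
        )
    if raw.get("ko_shifts") is not None:
        raw["ko_shifts"] = tuple(KoShift(**s) for s in raw["ko_shifts"])
    for key in ("groups", "timepoints"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
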