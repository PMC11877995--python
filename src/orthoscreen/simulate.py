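"""Synthetic two-species developmental time-course generator.

Emulates the sampling design of a mouse/zebrafish craniofacial
time-course experiment: six mouse stages (E8.5-E13.5) with 11 embryos
per stage (29 at E9.5) and five zebrafish stages (20 somites to 72 hpf)
with 16 pooled replicates per stage (8 at 32 hpf).  Genes fall into
four truth classes:

``reference``
    One pair per experiment (the Sox9 / sox9b roles) whose log2
    expression rises linearly from a low level to a plateau reached at
    a mid-course stage (E11.5 / 48 hpf by default).
``planted_correlated``
    Genes sharing the reference's profile shape in both species, up to
    a per-gene baseline offset and independent per-stage Gaussian
    perturbation (``profile_noise_sd`` log2 units).
``divergent_paralog``
    One-to-many pairs in which the species-B duplicate does *not* track
    the reference (its profile is the reversed ramp) while its sibling
    pair does — the sox9a/sox9b scenario.  The first such unit attaches
    the divergent duplicate to the reference gene itself; further units
    attach to planted genes.
``null``
    Genes whose per-species profiles are drawn independently of the
    reference shape.  To keep the truth labels meaningful, a null
    profile is redrawn (per species, independently) while its true
    correlation with the reference shape exceeds ``null_r_cap``; with
    the default cap of 0.5 a null gene can never truly pass a 0.7
    screen, so in the noiseless high-depth limit the screen recovers
    exactly the planted and reference pairs.

Read counts are negative binomial with mean equal to the
library-size-scaled linearized profile and size (inverse-dispersion)
parameter ``dispersion``; library sizes are log-normal around
``library_size_mean`` so that library-size normalization downstream is
non-trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, OrthologMap

logger = logging.getLogger(__name__)

MOUSE_STAGES = ("E8.5", "E9.5", "E10.5", "E11.5", "E12.5", "E13.5")
FISH_STAGES = ("20ss", "24hpf", "32hpf", "48hpf", "72hpf")
MOUSE_REPLICATES = (11, 29, 11, 11, 11, 11)
FISH_REPLICATES = (16, 16, 8, 16, 16)

TRUTH_CLASSES = ("reference", "planted_correlated", "divergent_paralog", "null")


@dataclass
class SimConfig:
    """Configuration of a simulated two-species time-course experiment.

    Stage labels, replicate counts and gene-class sizes default to the
    emulated study design (six mouse stages with 11/29 embryos, five
    zebrafish stages with 16/8 pooled replicates; 50 planted genes in a
    background of 950 nulls).  ``dispersion`` is the negative-binomial
    size parameter (variance = mu + mu^2/dispersion); the default of 10
    corresponds to a biological coefficient of variation of about 0.3,
    typical for bulk embryo RNA-seq.  ``profile_noise_sd`` (log2 units)
    controls how tightly planted genes track the reference shape; the
    default 0.25 yields true stage-profile correlations around 0.98.
    """

    stages_a: tuple[str, ...] = MOUSE_STAGES
    stages_b: tuple[str, ...] = FISH_STAGES
    replicates_a: tuple[int, ...] = MOUSE_REPLICATES
    replicates_b: tuple[int, ...] = FISH_REPLICATES
    n_null_genes: int = 950
    n_planted_genes: int = 50
    n_divergent_paralogs: int = 1
    library_size_mean: float = 1_000_000.0
    dispersion: float = 10.0
    profile_noise_sd: float = 0.25
    seed: int = 0
    # shape and magnitude of the reference trajectory (log2 units)
    rise_until_a: str = "E11.5"
    rise_until_b: str = "48hpf"
    amplitude: float = 3.0
    reference_base: float = 6.0
    baseline_range: tuple[float, float] = (4.0, 8.0)
    null_baseline_range: tuple[float, float] = (3.0, 9.0)
    null_profile_sd: float = 1.0
    null_r_cap: float | None = 0.5
    library_size_log_sd: float = 0.25
    reference_a: str = "Sox9"
    reference_b: str = "sox9b"

    def __post_init__(self) -> None:
        self.stages_a = tuple(self.stages_a)
        self.stages_b = tuple(self.stages_b)
        self.replicates_a = tuple(int(r) for r in self.replicates_a)
        self.replicates_b = tuple(int(r) for r in self.replicates_b)
        if len(self.replicates_a) != len(self.stages_a):
            raise ValueError("replicates_a must have one entry per stage in stages_a")
        if len(self.replicates_b) != len(self.stages_b):
            raise ValueError("replicates_b must have one entry per stage in stages_b")
        if min(self.replicates_a) < 1 or min(self.replicates_b) < 1:
            raise ValueError("every stage needs at least one replicate")
        if self.n_null_genes < 1:
            raise ValueError("n_null_genes must be a positive integer")
        if self.n_planted_genes < 0 or self.n_divergent_paralogs < 0:
            raise ValueError("gene class sizes must be non-negative")
        if self.n_divergent_paralogs > self.n_planted_genes + 1:
            raise ValueError(
                "n_divergent_paralogs may not exceed n_planted_genes + 1 "
                "(each divergent duplicate attaches to the reference or a planted gene)"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion (negative-binomial size) must be > 0")
        if self.profile_noise_sd < 0 or self.null_profile_sd < 0:
            raise ValueError("profile noise standard deviations must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be > 0")
        if self.rise_until_a not in self.stages_a:
            raise ValueError(f"unknown stage label {self.rise_until_a!r} for species A")
        if self.rise_until_b not in self.stages_b:
            raise ValueError(f"unknown stage label {self.rise_until_b!r} for species B")


@dataclass
class SimResult:
    """Simulated experiment: counts + metadata per species, pairing, truth.

    ``truth`` has one row per ortholog pair with its class label and the
    true per-stage mean log2 profiles of both genes (columns
    ``mu_a_<stage>`` / ``mu_b_<stage>``).
    """

    counts_a: CountMatrix
    counts_b: CountMatrix
    ortholog_map: OrthologMap
    truth: pd.DataFrame
    config: SimConfig


def make_reference_profile(
    stages: Sequence[str], rise_until: str, low: float, high: float
) -> np.ndarray:
    """Linear-ramp-then-plateau mean profile in log2 units.

    Expression starts at ``low``, increases linearly until the stage
    ``rise_until``, and stays at ``high`` thereafter (the trajectory
    observed for the reference gene: a gradual rise until mid-course,
    then a plateau).
    """
    stages = list(stages)
    if rise_until not in stages:
        raise ValueError(f"unknown stage label {rise_until!r}; stages are {stages}")
    if not low < high:
        raise ValueError(f"low must be strictly less than high (got {low} >= {high})")
    i = stages.index(rise_until)
    if i == 0:
        ramp = np.array([high])
    else:
        ramp = np.linspace(low, high, i + 1)
    plateau = np.full(len(stages) - i - 1, float(high))
    return np.concatenate([ramp, plateau])


def _profile_r(profile: np.ndarray, shape: np.ndarray) -> float:
    """Pearson r of a profile against the reference shape (nan if constant)."""
    p = profile - profile.mean()
    s = shape - shape.mean()
    denom = np.sqrt((p * p).sum() * (s * s).sum())
    if denom == 0:
        return float("nan")
    return float((p * s).sum() / denom)


def _draw_null_profiles(
    rng: np.random.Generator, n: int, shape: np.ndarray, cfg: SimConfig
) -> np.ndarray:
    """Null profiles independent of the reference, kept below null_r_cap.

    Baselines are uniform over ``null_baseline_range`` and stage
    deviations i.i.d. Gaussian.  Any profile whose true correlation with
    the reference shape exceeds the cap is redrawn (stage deviations
    only; the baseline does not affect correlation).  Rejection is
    applied per species independently, so across species the null
    profiles remain independent.
    """
    k = len(shape)
    lo, hi = cfg.null_baseline_range
    base = rng.uniform(lo, hi, size=n)
    prof = base[:, None] + rng.normal(0.0, cfg.null_profile_sd, size=(n, k))
    if cfg.null_r_cap is not None and cfg.null_profile_sd > 0:
        for _ in range(1000):
            r = np.array([_profile_r(row, shape) for row in prof])
            bad = np.where(np.nan_to_num(r, nan=-2.0) > cfg.null_r_cap)[0]
            if bad.size == 0:
                break
            prof[bad] = base[bad, None] + rng.normal(
                0.0, cfg.null_profile_sd, size=(bad.size, k)
            )
        else:  # pragma: no cover - would need a pathological cap
            raise RuntimeError("could not draw null profiles below null_r_cap")
    return prof


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, size: float
) -> np.ndarray:
    """Negative-binomial draws in the mean/size parameterization.

    ``size`` is the inverse-dispersion: variance = mean + mean^2/size.
    """
    mean = np.asarray(mean, dtype=float)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _species_counts(
    rng: np.random.Generator,
    profiles: pd.DataFrame,
    stages: Sequence[str],
    replicates: Sequence[int],
    cfg: SimConfig,
    species: str,
    prefix: str,
) -> CountMatrix:
    sample_ids, stage_labels, rep_idx, stage_idx = [], [], [], []
    for si, (stage, nrep) in enumerate(zip(stages, replicates)):
        for r in range(1, nrep + 1):
            sample_ids.append(f"{prefix}_{stage}_r{r:02d}")
            stage_labels.append(stage)
            rep_idx.append(r)
            stage_idx.append(si)
    n_samples = len(sample_ids)
    sig = cfg.library_size_log_sd
    lib = rng.lognormal(np.log(cfg.library_size_mean) - sig**2 / 2.0, sig, n_samples)
    frac = np.power(2.0, profiles.to_numpy())
    frac = frac / frac.sum(axis=0, keepdims=True)
    mu = frac[:, stage_idx] * lib[None, :]
    counts = nb_counts(rng, mu, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=profiles.index.rename("gene"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": species,
            "stage": stage_labels,
            "replicate": rep_idx,
        }
    )
    return CountMatrix(counts_df, meta, stage_order=tuple(stages))


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate a truth-labelled two-species time-course experiment.

    Returns counts and sample metadata for both species, the ortholog
    map linking them (including the one-to-many divergent-paralog
    pairs), and a truth table with each pair's class and true profiles.
    Identical configs (including seed) give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape_a = make_reference_profile(cfg.stages_a, cfg.rise_until_a, 0.0, cfg.amplitude)
    shape_b = make_reference_profile(cfg.stages_b, cfg.rise_until_b, 0.0, cfg.amplitude)
    ka, kb = len(cfg.stages_a), len(cfg.stages_b)
    lo, hi = cfg.baseline_range

    prof_a: dict[str, np.ndarray] = {}
    prof_b: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str, str]] = []  # gene_a, gene_b, class

    # reference pair
    prof_a[cfg.reference_a] = cfg.reference_base + shape_a
    prof_b[cfg.reference_b] = cfg.reference_base + shape_b
    pairs.append((cfg.reference_a, cfg.reference_b, "reference"))

    # planted correlated genes: reference shape + baseline offset + noise
    n_pl = cfg.n_planted_genes
    base_pa = rng.uniform(lo, hi, n_pl)
    base_pb = rng.uniform(lo, hi, n_pl)
    noise_pa = rng.normal(0.0, cfg.profile_noise_sd, (n_pl, ka))
    noise_pb = rng.normal(0.0, cfg.profile_noise_sd, (n_pl, kb))
    planted_a_names = [f"Corr{j:04d}" for j in range(1, n_pl + 1)]
    for j, name in enumerate(planted_a_names):
        prof_a[name] = base_pa[j] + shape_a + noise_pa[j]
        prof_b[name.lower() + "b"] = base_pb[j] + shape_b + noise_pb[j]
        pairs.append((name, name.lower() + "b", "planted_correlated"))

    # divergent paralogs: an extra species-B duplicate on the reversed ramp.
    # Unit 0 attaches to the reference gene (the sox9a role); unit j >= 1
    # attaches to planted gene j-1.
    n_dv = cfg.n_divergent_paralogs
    base_dv = rng.uniform(lo, hi, n_dv)
    noise_dv = rng.normal(0.0, cfg.profile_noise_sd, (n_dv, kb))
    reversed_b = cfg.amplitude - shape_b
    for j in range(n_dv):
        if j == 0:
            host_a = cfg.reference_a
            dup_name = cfg.reference_b[:-1] + "a" if cfg.reference_b.endswith("b") else cfg.reference_b + "_div"
        else:
            host_a = planted_a_names[j - 1]
            dup_name = host_a.lower() + "a"
        prof_b[dup_name] = base_dv[j] + reversed_b + noise_dv[j]
        pairs.append((host_a, dup_name, "divergent_paralog"))

    # null genes: independent profiles per species, capped away from the
    # reference shape so truth labels stay truthful
    n_nu = cfg.n_null_genes
    null_a = _draw_null_profiles(rng, n_nu, shape_a, cfg)
    null_b = _draw_null_profiles(rng, n_nu, shape_b, cfg)
    for j in range(n_nu):
        name = f"Null{j + 1:04d}"
        prof_a[name] = null_a[j]
        prof_b[name.lower()] = null_b[j]
        pairs.append((name, name.lower(), "null"))

    profiles_a = pd.DataFrame.from_dict(prof_a, orient="index", columns=list(cfg.stages_a))
    profiles_b = pd.DataFrame.from_dict(prof_b, orient="index", columns=list(cfg.stages_b))

    counts_a = _species_counts(
        rng, profiles_a, cfg.stages_a, cfg.replicates_a, cfg, "species_a", "A"
    )
    counts_b = _species_counts(
        rng, profiles_b, cfg.stages_b, cfg.replicates_b, cfg, "species_b", "B"
    )

    omap = OrthologMap([(a, b) for a, b, _ in pairs], provenance="simulated")
    truth = pd.DataFrame(
        {
            "gene_a": [a for a, _, _ in pairs],
            "gene_b": [b for _, b, _ in pairs],
            "label": [c for _, _, c in pairs],
        }
    )
    for i, st in enumerate(cfg.stages_a):
        truth[f"mu_a_{st}"] = [prof_a[a][i] for a, _, _ in pairs]
    for i, st in enumerate(cfg.stages_b):
        truth[f"mu_b_{st}"] = [prof_b[b][i] for _, b, _ in pairs]

    logger.info(
        "simulated experiment: %d species-A genes, %d species-B genes, %d pairs "
        "(planted=%d, divergent=%d, null=%d); profile_noise_sd=%.3g, null_profile_sd=%.3g",
        profiles_a.shape[0], profiles_b.shape[0], len(pairs),
        n_pl, n_dv, n_nu, cfg.profile_noise_sd, cfg.null_profile_sd,
    )
    return SimResult(counts_a, counts_b, omap, truth, cfg)


def gene_sets_from_truth(
    truth: pd.DataFrame,
    n_random_sets: int = 99,
    set_size_range: tuple[int, int] = (10, 30),
    seed: int = 0,
    planted_term: str = "PLANTED_MODULE",
) -> dict[str, tuple[str, list[str]]]:
    """Build a gene-set collection whose first set is the planted module.

    Returns a GMT-style mapping term -> (description, members) in which
    ``planted_term`` contains exactly the planted species-A genes and
    the remaining sets are uniform random draws from all species-A
    genes.  Used to exercise the enrichment stage on simulated runs.
    """
    rng = np.random.default_rng(seed)
    universe = truth["gene_a"].drop_duplicates().tolist()
    planted = truth.loc[truth["label"] == "planted_correlated", "gene_a"].tolist()
    sets: dict[str, tuple[str, list[str]]] = {}
    if planted:
        sets[planted_term] = ("planted reference-correlated module", planted)
    lo, hi = set_size_range
    for j in range(1, n_random_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = [universe[i] for i in rng.choice(len(universe), size=size, replace=False)]
        sets[f"RANDOM{j:03d}"] = (f"random set {j}", members)
    return sets
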