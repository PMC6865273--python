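"""Seeded synthetic-data generators with planted, known effect structure.

Every pipeline stage (essentialome calling, enrichment, age stratification,
cell-cycle DE, CDG sharing) can be exercised without the real screen /
expression / ortholog downloads: the generators emulate the study's data
shapes — a ~17,000-gene interrogated universe with a ~3.5% MIG fraction, a
multi-line binary essentiality matrix, a 4-stage replicated TPM table, and
five candidate-domestication-gene lists — while planting effects whose true
parameters are returned in a truth record, so downstream estimates can be
scored exactly.

All generators are pure functions of (config, seed) using numpy's PCG64
generator; the same seed gives identical output on any platform.

Essentiality model
------------------
Each gene gets a latent consensus essentiality draw: base odds
``base_essential_rate/(1-base_essential_rate)``, multiplied by
``ancient_odds_multiplier`` for ancient genes (ancient genes are more often
essential) and by the planted MIG odds ratio (optionally per age stratum).
Per cell line the consensus is corrupted: essential genes drop out of a
line's essentialome with probability ``dropout_rate``, non-essential genes
are spuriously called with probability ``spurious_call_rate``.  Dropouts
create the core ⊂ majority ⊂ total separation; the spurious rate is kept
small so the total essentialome's composition still reflects the planted
odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cellcycle import DEFAULT_STAGES, ExpressionTable
from .domestication import CDGCollection
from .essentialome import EssentialityMatrix
from .gene_age import DEFAULT_LADDER, CladeLadder, GeneAgeMap
from .genes import GeneAnnotation, GeneList, GeneUniverse

__all__ = [
    "SyntheticConfig",
    "DEFAULT_CLADE_PROBS",
    "generate_universe",
    "generate_essentiality",
    "generate_expression",
    "generate_cdg_lists",
    "age_map_from_universe",
]

#: Default clade probabilities for the interrogated universe: about two thirds
#: of interrogated genes trace back to LECA, the rest spread over younger
#: clades with a thin species-specific tail.
DEFAULT_CLADE_PROBS: dict[str, float] = {
    "Eukaryota": 0.668,
    "Opisthokonta": 0.060,
    "Metazoa": 0.060,
    "Eumetazoa": 0.050,
    "Bilateria": 0.050,
    "Deuterostomia": 0.020,
    "Chordata": 0.030,
    "Euteleostomi": 0.030,
    "Amniota": 0.010,
    "species_specific": 0.022,
}

DEFAULT_SPECIES: tuple[str, ...] = ("dog", "cat", "cattle", "horse", "human")

#: Per-species CDG list sizes; the human list dominates, mirroring the real
#: five-species collection (union ~1,386 genes).
DEFAULT_CDG_SIZES: dict[str, int] = {
    "dog": 175,
    "cat": 175,
    "cattle": 175,
    "horse": 176,
    "human": 742,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with defaults matching its scale."""

    # universe
    n_genes: int = 17_000
    mig_fraction: float = 0.035
    clade_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLADE_PROBS))
    ladder: CladeLadder = DEFAULT_LADDER
    mig_family_sizes: tuple[int, ...] = (3, 2, 2)
    # essentiality
    n_lines: int = 50
    base_essential_rate: float = 0.10
    planted_odds_ratio: float = 2.5
    stratified_odds_ratios: Optional[Mapping[str, float]] = None  # {"ancient": ..., "younger": ...}
    ancient_odds_multiplier: float = 1.5
    dropout_rate: float = 0.02
    spurious_call_rate: float = 0.0002
    n_line_groups: int = 5
    # expression
    n_replicates: int = 3
    tpm_log2_mean: float = 3.0
    tpm_log2_sd: float = 2.0
    replicate_cv: float = 0.05
    de_fraction: float = 0.01
    de_fold: float = 4.0
    # domestication
    species: tuple[str, ...] = DEFAULT_SPECIES
    cdg_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CDG_SIZES))
    planted_cdg_mig_odds_ratio: float = 1.5
    n_shared_two: int = 45
    n_shared_three: int = 6
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.clade_probs.get(c, 0.0) for c in self.ladder.clades])
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("clade_probs must be non-negative and sum to 1 over the ladder")
        for name, value in (
            ("mig_fraction", self.mig_fraction),
            ("base_essential_rate", self.base_essential_rate),
            ("dropout_rate", self.dropout_rate),
            ("spurious_call_rate", self.spurious_call_rate),
            ("de_fraction", self.de_fraction),
        ):
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name, value in (
            ("planted_odds_ratio", self.planted_odds_ratio),
            ("planted_cdg_mig_odds_ratio", self.planted_cdg_mig_odds_ratio),
            ("de_fold", self.de_fold),
            ("ancient_odds_multiplier", self.ancient_odds_multiplier),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.n_genes, self.n_lines, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if any(s < 2 for s in self.mig_family_sizes):
            raise ValueError("MIG families must have size >= 2")


def _rng(config: SyntheticConfig, seed: Optional[int], stream: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([base, stream])


def generate_universe(config: SyntheticConfig, seed: Optional[int] = None) -> GeneUniverse:
    """A synthetic interrogated universe with MIG flags, ages and MIG families."""
    rng = _rng(config, seed, 1)
    n = config.n_genes
    symbols = [f"G{i:06d}" for i in range(n)]
    is_mig = rng.random(n) < config.mig_fraction
    probs = np.array([config.clade_probs.get(c, 0.0) for c in config.ladder.clades])
    ages = rng.choice(len(config.ladder.clades), size=n, p=probs)

    # MIG families: disjoint groups of MIGs that descend from one ancestral MIG
    family: dict[int, str] = {}
    mig_idx = np.flatnonzero(is_mig)
    needed = sum(config.mig_family_sizes)
    if needed and len(mig_idx) >= needed:
        chosen = rng.choice(mig_idx, size=needed, replace=False)
        pos = 0
        for f, size in enumerate(config.mig_family_sizes):
            for j in chosen[pos : pos + size]:
                family[int(j)] = f"FAM{f + 1}"
            pos += size

    annotations = {
        symbols[i]: GeneAnnotation(
            is_mig=bool(is_mig[i]),
            family=family.get(i),
            age_clade=config.ladder.clades[ages[i]],
        )
        for i in range(n)
    }
    return GeneUniverse(
        interrogated=GeneList(name="synthetic interrogated genes", members=tuple(symbols)),
        annotations=annotations,
    )


def age_map_from_universe(universe: GeneUniverse) -> GeneAgeMap:
    """Turn the universe's age annotations into a GeneAgeMap (nothing unassigned)."""
    ages = {g: universe.annotations[g].age_clade for g in universe.interrogated}
    missing = [g for g, a in ages.items() if a is None]
    if missing:
        raise ValueError(f"{len(missing)} genes lack an age annotation")
    return GeneAgeMap(ages=ages)  # type: ignore[arg-type]


def _consensus_probability(config: SyntheticConfig, is_mig: np.ndarray, ancient: np.ndarray) -> np.ndarray:
    base = config.base_essential_rate
    odds = np.full(is_mig.shape, base / (1 - base))
    odds[ancient] *= config.ancient_odds_multiplier
    if config.stratified_odds_ratios is not None:
        or_anc = config.stratified_odds_ratios.get("ancient", 1.0)
        or_yng = config.stratified_odds_ratios.get("younger", 1.0)
        odds[is_mig & ancient] *= or_anc
        odds[is_mig & ~ancient] *= or_yng
    else:
        odds[is_mig] *= config.planted_odds_ratio
    return odds / (1 + odds)


def generate_essentiality(
    universe: GeneUniverse, config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[EssentialityMatrix, dict]:
    """A calls-mode essentiality matrix with a planted MIG odds ratio, plus truth.

    The truth record stores the consensus calls and every planted parameter,
    sufficient to score enrichment and parameter-recovery downstream.
    """
    rng = _rng(config, seed, 2)
    genes = list(universe.interrogated)
    n = len(genes)
    is_mig = np.array([universe.annotations[g].is_mig for g in genes])
    ladder = config.ladder
    ancient = np.array(
        [
            universe.annotations[g].age_clade is not None
            and ladder.is_ancient(universe.annotations[g].age_clade)  # type: ignore[arg-type]
            for g in genes
        ]
    )
    p_consensus = _consensus_probability(config, is_mig, ancient)
    consensus = rng.random(n) < p_consensus

    L = config.n_lines
    u = rng.random((n, L))
    calls = np.where(
        consensus[:, None],
        (u >= config.dropout_rate).astype(float),  # essential gene drops out with prob dropout
        (u < config.spurious_call_rate).astype(float),
    )
    lines = [f"LINE{j:03d}" for j in range(L)]
    group_of = {line: f"TYPE{j % config.n_line_groups}" for j, line in enumerate(lines)}
    matrix = EssentialityMatrix(
        values=pd.DataFrame(calls, index=genes, columns=lines),
        mode="calls",
        line_groups=group_of,
    )
    truth = {
        "consensus_essential": {g: bool(c) for g, c in zip(genes, consensus)},
        "planted_odds_ratio": config.planted_odds_ratio,
        "stratified_odds_ratios": dict(config.stratified_odds_ratios or {}),
        "base_essential_rate": config.base_essential_rate,
        "ancient_odds_multiplier": config.ancient_odds_multiplier,
        "dropout_rate": config.dropout_rate,
        "spurious_call_rate": config.spurious_call_rate,
    }
    return matrix, truth


def generate_expression(
    universe: GeneUniverse, config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[ExpressionTable, dict]:
    """A 4-stage replicated TPM table with a planted fraction of DE genes.

    Each gene has a log-normal baseline shared across stages; a ``de_fraction``
    of genes take a ``de_fold`` step (up or down) at one randomly chosen
    successive stage boundary.  Replicate noise is multiplicative log-normal
    with coefficient of variation ``replicate_cv``.
    """
    rng = _rng(config, seed, 3)
    genes = list(universe.interrogated)
    n = len(genes)
    stages = DEFAULT_STAGES
    n_stages = len(stages)

    baseline = np.exp2(rng.normal(config.tpm_log2_mean, config.tpm_log2_sd, size=n))
    stage_mean = np.tile(baseline[:, None], (1, n_stages))

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_pair = rng.integers(0, n_stages - 1, size=n_de)
    de_up = rng.random(n_de) < 0.5
    for gi, pair, up in zip(de_idx, de_pair, de_up):
        factor = config.de_fold if up else 1.0 / config.de_fold
        stage_mean[gi, pair + 1 :] *= factor  # step at the chosen boundary

    sigma = np.sqrt(np.log1p(config.replicate_cv**2))
    reps = config.n_replicates
    noise = np.exp(rng.normal(0.0, sigma, size=(n, n_stages, reps)) - sigma**2 / 2)
    tpm = stage_mean[:, :, None] * noise

    columns = pd.MultiIndex.from_tuples(
        [(s, f"rep{r + 1}") for s in stages for r in range(reps)], names=["stage", "replicate"]
    )
    df = pd.DataFrame(tpm.reshape(n, n_stages * reps), index=genes, columns=columns)
    truth = {
        "de_genes": {
            genes[gi]: {"pair": f"{stages[p]}->{stages[p + 1]}", "direction": "up" if up else "down"}
            for gi, p, up in zip(de_idx, de_pair, de_up)
        },
        "de_fraction": config.de_fraction,
        "de_fold": config.de_fold,
        "replicate_cv": config.replicate_cv,
    }
    return ExpressionTable(tpm=df, stages=stages), truth


def generate_cdg_lists(
    universe: GeneUniverse, config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[CDGCollection, dict]:
    """Five species CDG lists with planted 2-/3-species sharing and MIG enrichment.

    Genes are sampled without replacement with weights proportional to the
    planted MIG odds ratio; a configured number of genes are planted into
    exactly two / exactly three species, and the remaining (filler) genes are
    dealt disjointly across species so no accidental sharing arises — the
    planted shared sets are recovered exactly.
    """
    rng = _rng(config, seed, 4)
    genes = np.array(list(universe.interrogated))
    sizes = {sp: int(config.cdg_sizes[sp]) for sp in config.species}
    n_two, n_three = config.n_shared_two, config.n_shared_three
    total_memberships = sum(sizes.values())
    n_unique = total_memberships - n_two - 2 * n_three
    if n_unique > len(genes):
        raise ValueError("cdg sizes exceed the number of genes in the universe")

    is_mig = np.array([universe.annotations[g].is_mig for g in genes])
    weights = np.where(is_mig, config.planted_cdg_mig_odds_ratio, 1.0)
    pool = rng.choice(genes, size=n_unique, replace=False, p=weights / weights.sum())

    shared3, pool = list(pool[:n_three]), pool[n_three:]
    shared2, pool = list(pool[:n_two]), pool[n_two:]

    lists: dict[str, list[str]] = {sp: [] for sp in config.species}
    n_species = len(config.species)
    for g in shared3:
        for sp_i in rng.choice(n_species, size=3, replace=False):
            lists[config.species[sp_i]].append(str(g))
    for g in shared2:
        for sp_i in rng.choice(n_species, size=2, replace=False):
            lists[config.species[sp_i]].append(str(g))
    # deal the remaining pool disjointly, topping each species up to its size
    cursor = 0
    for sp in config.species:
        need = sizes[sp] - len(lists[sp])
        if need < 0:
            raise ValueError(f"species {sp!r} list size {sizes[sp]} too small for planted sharing")
        lists[sp].extend(str(g) for g in pool[cursor : cursor + need])
        cursor += need
    if cursor != len(pool):  # pragma: no cover - arithmetic guard
        raise AssertionError("filler pool not fully consumed")

    collection = CDGCollection(
        species_lists={
            sp: GeneList(name=f"CDG[{sp}]", members=tuple(lists[sp]), provenance="synthetic")
            for sp in config.species
        }
    )
    truth = {
        "shared_three": sorted(str(g) for g in shared3),
        "shared_two": sorted(str(g) for g in shared2),
        "planted_cdg_mig_odds_ratio": config.planted_cdg_mig_odds_ratio,
    }
    return collection, truth
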