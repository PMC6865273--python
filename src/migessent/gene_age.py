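"""Phylostratigraphic gene-age assignment from ortholog-group membership.

Each gene is dated by the oldest taxonomic clade at which it belongs to an
orthologous group (eggNOG-style input: gene -> {(group id, clade)}).  A
clade ladder orders clades from oldest to youngest and marks an "ancient"
boundary; genes tracing back to the last eukaryotic common ancestor (LECA)
or earlier are ancient, everything that emerged in Opisthokonta or later is
younger.  Genes with no ortholog group at all are placed in the youngest
(species-specific) rung — absence of detectable orthologs is the standard
phylostratigraphic signal of recency — and flagged as unassigned; a strict
mode drops them instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .enrichment import EnrichmentResult, test_enrichment
from .genes import GeneId, GeneList, GeneUniverse, normalize_symbol

__all__ = [
    "DEFAULT_LADDER",
    "CladeLadder",
    "OrthologMembership",
    "GeneAgeMap",
    "read_membership",
    "read_ladder",
    "assign_gene_age",
    "assign_ages",
    "partition_by_age",
    "age_distribution",
    "age_stratified_enrichment",
]


@dataclass(frozen=True)
class CladeLadder:
    """Ordered clade labels, oldest to youngest, with an ancient/younger boundary."""

    clades: tuple[str, ...]
    ancient_boundary: str

    def __post_init__(self) -> None:
        if len(set(self.clades)) != len(self.clades):
            raise ValueError("clade labels must be unique")
        if self.ancient_boundary not in self.clades:
            raise ValueError(f"ancient_boundary {self.ancient_boundary!r} not in ladder")

    def rank(self, clade: str) -> int:
        try:
            return self.clades.index(clade)
        except ValueError:
            raise KeyError(f"clade {clade!r} not in ladder {self.clades}") from None

    def is_ancient(self, clade: str) -> bool:
        return self.rank(clade) <= self.rank(self.ancient_boundary)

    @property
    def youngest(self) -> str:
        return self.clades[-1]


#: Default ladder: Eukaryota collapses everything at or before LECA into one
#: oldest rung; the boundary sits there, so "ancient" = Eukaryota.
DEFAULT_LADDER = CladeLadder(
    clades=(
        "Eukaryota",
        "Opisthokonta",
        "Metazoa",
        "Eumetazoa",
        "Bilateria",
        "Deuterostomia",
        "Chordata",
        "Euteleostomi",
        "Amniota",
        "species_specific",
    ),
    ancient_boundary="Eukaryota",
)


@dataclass(frozen=True)
class OrthologMembership:
    """gene -> set of (ortholog group id, clade label) pairs."""

    records: Mapping[GeneId, frozenset[tuple[str, str]]]

    def clades_of(self, gene: GeneId) -> set[str]:
        return {clade for _gid, clade in self.records.get(gene, frozenset())}


@dataclass(frozen=True)
class GeneAgeMap:
    """Resolved clade per gene, plus the genes that had no ortholog membership."""

    ages: Mapping[GeneId, str]
    unassigned: frozenset[GeneId] = frozenset()

    def age_of(self, gene: GeneId) -> Optional[str]:
        return self.ages.get(gene)


def read_membership(path: str | Path) -> OrthologMembership:
    """Read a TSV with columns gene, group_id, clade into an OrthologMembership."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"gene", "group_id", "clade"}
    if not expected.issubset(df.columns):
        raise ValueError(f"membership file {path} must have columns {sorted(expected)}")
    records: dict[GeneId, set[tuple[str, str]]] = {}
    for gene, gid, clade in df[["gene", "group_id", "clade"]].itertuples(index=False):
        records.setdefault(normalize_symbol(gene), set()).add((gid, clade))
    return OrthologMembership(records={g: frozenset(s) for g, s in records.items()})


def read_ladder(path: str | Path) -> CladeLadder:
    """Read a YAML ladder: {clades: [oldest, ..., youngest], ancient_boundary: label}."""
    data = yaml.safe_load(Path(path).read_text())
    return CladeLadder(clades=tuple(data["clades"]), ancient_boundary=data["ancient_boundary"])


def assign_gene_age(
    gene: GeneId, membership: OrthologMembership, ladder: CladeLadder = DEFAULT_LADDER
) -> str:
    """The oldest clade among a gene's ortholog groups; youngest rung if none."""
    clades = membership.clades_of(gene)
    if not clades:
        return ladder.youngest
    for clade in clades:
        if clade not in ladder.clades:
            raise ValueError(f"membership cites clade {clade!r} absent from the ladder")
    return min(clades, key=ladder.rank)


def assign_ages(
    genes: Iterable[GeneId],
    membership: OrthologMembership,
    ladder: CladeLadder = DEFAULT_LADDER,
) -> GeneAgeMap:
    """Resolve an age for every gene; genes with no membership are flagged unassigned."""
    ages: dict[GeneId, str] = {}
    unassigned: set[GeneId] = set()
    for gene in genes:
        if not membership.clades_of(gene):
            unassigned.add(gene)
        ages[gene] = assign_gene_age(gene, membership, ladder)
    return GeneAgeMap(ages=ages, unassigned=frozenset(unassigned))


def partition_by_age(
    genes: GeneList,
    age_map: GeneAgeMap,
    ladder: CladeLadder = DEFAULT_LADDER,
    *,
    strict: bool = False,
) -> tuple[GeneList, GeneList]:
    """Split a gene list into (ancient, younger) at the ladder's boundary.

    Unassigned genes count as younger (they sit in the youngest rung); with
    ``strict=True`` they are dropped from both outputs instead.
    """
    ancient: list[GeneId] = []
    younger: list[GeneId] = []
    for g in genes:
        if g in age_map.unassigned:
            if not strict:
                younger.append(g)
            continue
        age = age_map.age_of(g)
        if age is None:
            raise ValueError(f"gene {g} has no age and is not flagged unassigned")
        (ancient if ladder.is_ancient(age) else younger).append(g)
    return (
        GeneList(name=f"{genes.name} (ancient)", members=tuple(ancient), provenance=genes.provenance),
        GeneList(name=f"{genes.name} (younger)", members=tuple(younger), provenance=genes.provenance),
    )


def age_distribution(
    genes: GeneList, age_map: GeneAgeMap, ladder: CladeLadder = DEFAULT_LADDER
) -> pd.DataFrame:
    """Per-clade gene counts and percentages, ordered oldest to youngest.

    Counts always sum to the input size (unassigned genes land in the
    youngest rung, where assign_ages put them).
    """
    counts = {clade: 0 for clade in ladder.clades}
    for g in genes:
        age = age_map.age_of(g)
        if age is None:
            raise ValueError(f"gene {g} missing from the age map")
        counts[age] += 1
    total = len(genes)
    return pd.DataFrame(
        {
            "clade": list(ladder.clades),
            "count": [counts[c] for c in ladder.clades],
            "percent": [100 * counts[c] / total if total else 0.0 for c in ladder.clades],
        }
    )


def age_stratified_enrichment(
    query: GeneList,
    feature: GeneList,
    universe: GeneUniverse,
    age_map: GeneAgeMap,
    stratum: str,
    ladder: CladeLadder = DEFAULT_LADDER,
    convention: str = "universe_includes_query",
) -> EnrichmentResult:
    """Enrichment of feature in query restricted to the ancient or younger stratum.

    Removing age as a variable: universe, query and feature are all cut down
    to genes of the requested stratum before the exact test runs, so e.g.
    ancient MIGs are tested within the ancient essentialome against ancient
    interrogated genes only.
    """
    if stratum not in ("ancient", "younger"):
        raise ValueError("stratum must be 'ancient' or 'younger'")
    idx = 0 if stratum == "ancient" else 1

    uni_strata = partition_by_age(universe.interrogated, age_map, ladder)
    stratum_genes = uni_strata[idx]
    if len(stratum_genes) == 0:
        raise ValueError(f"the {stratum} stratum of the universe is empty")
    stratum_universe = GeneUniverse(
        interrogated=GeneList(
            name=f"{universe.interrogated.name} ({stratum})",
            members=stratum_genes.members,
        ),
        annotations={g: universe.annotations[g] for g in stratum_genes},
    )
    q_strat = partition_by_age(query, age_map, ladder)[idx]
    f_strat = partition_by_age(feature, age_map, ladder)[idx]
    return test_enrichment(q_strat, f_strat, stratum_universe, convention)
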