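"""Cross-species candidate-domestication-gene (CDG) sharing and gain-event counting.

Domestication syndromes across dog, cat, cattle, horse and (self-domesticated)
human leave overlapping selection signatures; genes under putative selection
in several species are the interesting ones.  This module counts CDGs shared
by at least (or exactly) k species, reports overlaps with MIG and
essentialome lists, and collapses minor-intron-rich gene families to single
minor-intron gain events: paralogous MIGs descended from one ancestral MIG
(e.g. a family of 3 MIGs) represent one gain, so the event count is
(genes outside any family) + (families with at least one member present).

Enrichment of MIGs among CDGs is tested against the fixed genome background
(648 MIGs of 20,444 protein-coding genes) via the enrichment module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

from .enrichment import ContingencyTable, EnrichmentResult, enrichment_test
from .genes import GeneId, GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "GENOME_BACKGROUND",
    "CDGCollection",
    "FamilyMap",
    "shared_cdg",
    "overlap_report",
    "collapse_gain_events",
    "cdg_mig_enrichment",
]

#: MIGs among human protein-coding genes: the fixed genome-wide background
#: used for CDG enrichment tests (distinct from the CRISPR-screen universe).
GENOME_BACKGROUND = {"K": 648, "N": 20444}


@dataclass(frozen=True)
class CDGCollection:
    """Per-species candidate-domestication-gene lists."""

    species_lists: Mapping[str, GeneList]

    def __post_init__(self) -> None:
        if not self.species_lists:
            raise ValueError("need at least one species list")

    @property
    def species(self) -> list[str]:
        return list(self.species_lists)

    def union(self) -> frozenset[GeneId]:
        return frozenset().union(*(gl.member_set for gl in self.species_lists.values()))

    def species_count(self) -> dict[GeneId, int]:
        """Number of species lists each gene appears in."""
        counts: dict[GeneId, int] = {}
        for gl in self.species_lists.values():
            for g in gl.member_set:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass(frozen=True)
class FamilyMap:
    """Disjoint gene families (family label -> member genes), each non-empty."""

    families: Mapping[str, frozenset[GeneId]]

    def __post_init__(self) -> None:
        seen: set[GeneId] = set()
        for fam, members in self.families.items():
            if not members:
                raise ValueError(f"family {fam!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"families overlap on genes {sorted(overlap)}")
            seen |= set(members)


def shared_cdg(collection: CDGCollection, min_species: int = 2, *, exact: bool = False) -> GeneList:
    """Genes present in at least (or, with ``exact=True``, exactly) min_species lists.

    ``min_species=1`` gives the union.  A cutoff above the number of species
    yields an empty list with a warning rather than an error.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    n_species = len(collection.species_lists)
    if min_species > n_species:
        warnings.warn(
            f"min_species={min_species} exceeds the {n_species} species provided; "
            "result is empty",
            stacklevel=2,
        )
    counts = collection.species_count()
    if exact:
        members = sorted(g for g, c in counts.items() if c == min_species)
        label = f"=={min_species}"
    else:
        members = sorted(g for g, c in counts.items() if c >= min_species)
        label = f">={min_species}"
    return GeneList(
        name=f"CDGs shared by {label} species",
        members=tuple(members),
        provenance=f"{n_species} species lists",
    )


def overlap_report(set_a: GeneList, set_b: GeneList) -> dict[str, Optional[float]]:
    """|A ∩ B| and 100·|A ∩ B|/|A| (two decimals); percentage absent when |A| = 0."""
    count = set_a.intersection_count(set_b)
    if len(set_a) == 0:
        return {"count": count, "percentage": None}
    return {"count": count, "percentage": round(100 * count / len(set_a), 2)}


def collapse_gain_events(migs: GeneList, families: FamilyMap) -> int:
    """Collapse family members to one minor-intron gain event per family.

    count = (MIGs in no family) + (families with >= 1 member among the MIGs).
    Family members not present in ``migs`` are ignored with a warning.
    """
    mig_set = migs.member_set
    in_family: set[GeneId] = set()
    families_hit = 0
    for fam, members in families.families.items():
        stray = members - mig_set
        if stray:
            warnings.warn(
                f"family {fam!r} members not in the gene list ignored: {sorted(stray)}",
                stacklevel=2,
            )
        present = members & mig_set
        if present:
            families_hit += 1
            in_family |= present
    singletons = len(mig_set - in_family)
    return singletons + families_hit


def cdg_mig_enrichment(
    cdgs: GeneList,
    migs: GeneList,
    background: Mapping[str, int] = GENOME_BACKGROUND,
) -> EnrichmentResult:
    """Fisher test of MIG over-representation in a CDG list vs the genome background.

    The background is supplied as fixed counts (default 648 MIGs of 20,444
    protein-coding genes) rather than an explicit gene universe, because the
    full protein-coding list is not part of the inputs; k is counted from the
    actual gene lists.
    """
    k = cdgs.intersection_count(migs)
    table = ContingencyTable(
        N=background["N"],
        K=background["K"],
        n=len(cdgs),
        k=k,
        feature_label=migs.name,
        query_label=cdgs.name,
        universe_label=f"genome ({background['K']}/{background['N']})",
    )
    return enrichment_test(table)
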