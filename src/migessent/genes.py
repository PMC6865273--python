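"""Gene identifiers, gene lists, the interrogated universe, and file I/O.

All analyses in this package are keyed on normalized gene symbols
(uppercase, whitespace-stripped).  Every list read from disk is normalized
and de-duplicated on entry so that set operations downstream are exact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneId",
    "GeneList",
    "GeneAnnotation",
    "GeneUniverse",
    "PipelineConfig",
    "normalize_symbol",
    "normalize_gene_ids",
    "read_gene_list",
    "write_gene_list",
    "read_matrix",
    "restrict_to_universe",
]

#: A gene identifier is a normalized symbol (plain string).
GeneId = str

_SYMBOL_RE = re.compile(r"^[A-Z0-9][A-Z0-9_.\-@]*$")


def normalize_symbol(raw: str, *, alias_map: Optional[Mapping[str, str]] = None) -> GeneId:
    """Normalize a raw gene symbol: strip whitespace, uppercase, apply aliases.

    Idempotent: normalizing an already-normalized symbol returns it unchanged.

    Raises
    ------
    ValueError
        If ``raw`` is not a string or normalizes to the empty string.
    """
    if not isinstance(raw, str):
        raise ValueError(f"gene symbol must be text, got {type(raw).__name__}")
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def normalize_gene_ids(
    raw: Iterable[str], *, alias_map: Optional[Mapping[str, str]] = None
) -> list[GeneId]:
    """Normalize a collection of raw symbols, collapsing duplicates to first occurrence.

    Order is preserved.  Empty or non-text items raise a ``ValueError`` naming
    the offending index.
    """
    seen: set[GeneId] = set()
    out: list[GeneId] = []
    for i, item in enumerate(raw):
        try:
            sym = normalize_symbol(item, alias_map=alias_map)
        except ValueError as exc:
            raise ValueError(f"invalid gene symbol at index {i}: {exc}") from None
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


@dataclass(frozen=True)
class GeneList:
    """A named, ordered, duplicate-free collection of gene symbols."""

    name: str
    members: tuple[GeneId, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        members = tuple(normalize_gene_ids(self.members))
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "_member_set", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: object) -> bool:
        return gene in self._member_set  # type: ignore[attr-defined]

    def __iter__(self):
        return iter(self.members)

    @property
    def member_set(self) -> frozenset[GeneId]:
        return self._member_set  # type: ignore[attr-defined]

    def intersection_count(self, other: "GeneList | set[GeneId] | frozenset[GeneId]") -> int:
        other_set = other.member_set if isinstance(other, GeneList) else frozenset(other)
        return len(self.member_set & other_set)


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation inside a :class:`GeneUniverse`."""

    is_mig: bool
    family: Optional[str] = None
    age_clade: Optional[str] = None


@dataclass(frozen=True)
class GeneUniverse:
    """The interrogated gene set with per-gene annotations.

    Every annotated gene must be a member of ``interrogated``, and the MIG
    flag must be defined for every member.
    """

    interrogated: GeneList
    annotations: Mapping[GeneId, GeneAnnotation]

    def __post_init__(self) -> None:
        members = self.interrogated.member_set
        extra = set(self.annotations) - members
        if extra:
            raise ValueError(
                f"{len(extra)} annotated genes are not in the interrogated list "
                f"(e.g. {sorted(extra)[:3]})"
            )
        missing = members - set(self.annotations)
        if missing:
            raise ValueError(
                f"is_mig undefined for {len(missing)} interrogated genes "
                f"(e.g. {sorted(missing)[:3]})"
            )

    def __len__(self) -> int:
        return len(self.interrogated)

    def __contains__(self, gene: object) -> bool:
        return gene in self.interrogated

    @property
    def migs(self) -> GeneList:
        """The MIG members of the universe, in interrogated order."""
        return GeneList(
            name="MIGs",
            members=tuple(g for g in self.interrogated if self.annotations[g].is_mig),
            provenance="is_mig annotations of the universe",
        )

    def ages(self) -> dict[GeneId, Optional[str]]:
        return {g: self.annotations[g].age_clade for g in self.interrogated}

    def families(self) -> dict[str, set[GeneId]]:
        fams: dict[str, set[GeneId]] = {}
        for g in self.interrogated:
            fam = self.annotations[g].family
            if fam is not None:
                fams.setdefault(fam, set()).add(g)
        return fams


@dataclass(frozen=True)
class PipelineConfig:
    """Shared thresholds and conventions for a full analysis run.

    Parameters
    ----------
    essentiality_threshold:
        Score cutoff for calling a gene essential in a cell line (call = 1
        iff score <= threshold, boundary inclusive), or the string
        ``"precalled"`` when the input matrix already holds binary calls.
    majority_fraction:
        Fraction of cell lines a gene must be essential in to enter the
        majority essentialome (default 0.95, i.e. ">= 95% of lines").
    tpm_threshold:
        Expression cutoff; a stage counts as expressed iff mean TPM >= this
        (default 1.0).
    de_alpha:
        Significance level for successive-stage differential expression
        (default 0.05).
    background_convention:
        Whether the query set is part of the enrichment background
        (``universe_includes_query``, the default) or removed from it.
    """

    essentiality_threshold: float | str = "precalled"
    majority_fraction: float = 0.95
    tpm_threshold: float = 1.0
    de_alpha: float = 0.05
    background_convention: str = "universe_includes_query"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.essentiality_threshold, str):
            if self.essentiality_threshold != "precalled":
                raise ValueError("essentiality_threshold must be a number or 'precalled'")
        elif not _finite(self.essentiality_threshold):
            raise ValueError("essentiality_threshold must be finite")
        if not (0 < self.majority_fraction <= 1):
            raise ValueError("majority_fraction must be in (0, 1]")
        if not _finite(self.tpm_threshold):
            raise ValueError("tpm_threshold must be finite")
        if not (0 < self.de_alpha < 1):
            raise ValueError("de_alpha must be in (0, 1)")
        if self.background_convention not in (
            "universe_includes_query",
            "universe_excludes_query",
        ):
            raise ValueError(f"unknown background convention {self.background_convention!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _finite(x: float) -> bool:
    import math

    return isinstance(x, (int, float)) and math.isfinite(x)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_gene_list(
    path: str | Path,
    format: str = "single_column_tsv",
    *,
    header: Optional[bool] = None,
    alias_map: Optional[Mapping[str, str]] = None,
) -> GeneList | list[GeneList]:
    """Read gene list(s) from a single-column TSV or a GMT file.

    For ``single_column_tsv`` one :class:`GeneList` is returned; ``header``
    controls whether the first line is skipped (``None`` auto-detects: the
    first line is treated as a header iff it does not look like a gene
    symbol).  For ``gmt`` a list of GeneLists is returned in file order.
    """
    path = Path(path)
    if format == "single_column_tsv":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if header is None:
            header = bool(lines) and not _SYMBOL_RE.match(lines[0].strip().upper())
        if header and lines:
            lines = lines[1:]
        members = normalize_gene_ids(lines, alias_map=alias_map)
        logger.info("read %d genes from %s", len(members), path)
        return GeneList(name=path.stem, members=tuple(members), provenance=str(path))
    if format == "gmt":
        out: list[GeneList] = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (<2 tab fields)")
            name, _desc, *genes = fields
            members = normalize_gene_ids([g for g in genes if g.strip()], alias_map=alias_map)
            out.append(GeneList(name=name, members=tuple(members), provenance=f"{path}:{lineno}"))
        logger.info("read %d gene sets from %s", len(out), path)
        return out
    raise ValueError(f"unknown gene-list format {format!r}")


def write_gene_list(gene_list: GeneList, path: str | Path, format: str = "single_column_tsv") -> None:
    """Write a GeneList as single-column TSV or as one GMT line."""
    path = Path(path)
    if format == "single_column_tsv":
        path.write_text("\n".join(gene_list.members) + ("\n" if gene_list.members else ""))
    elif format == "gmt":
        desc = gene_list.provenance or "."
        path.write_text("\t".join([gene_list.name, desc, *gene_list.members]) + "\n")
    else:
        raise ValueError(f"unknown gene-list format {format!r}")


def read_matrix(path: str | Path, *, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a genes x columns numeric matrix (CSV/TSV, first column = gene label).

    Row labels are normalized gene symbols; column labels are preserved
    verbatim.  Empty cells stay missing (NaN) — they are never coerced to 0.
    Duplicate gene rows (after normalization) are an error.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [normalize_symbol(str(g)) for g in df.index]
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene rows in {path}: {dup}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric columns in {path}: {non_numeric}")
    logger.info("read %dx%d matrix from %s", df.shape[0], df.shape[1], path)
    return df


def restrict_to_universe(gene_list: GeneList, universe: GeneUniverse) -> GeneList:
    """Intersect a gene list with the interrogated universe, preserving list order.

    The provenance note records member counts before and after restriction —
    the step that turns e.g. a full database MIG list into the interrogated
    MIG list.
    """
    before = len(gene_list)
    kept = tuple(g for g in gene_list if g in universe)
    prov = (
        f"{gene_list.provenance + '; ' if gene_list.provenance else ''}"
        f"restricted to universe {universe.interrogated.name!r}: {before} -> {len(kept)}"
    )
    logger.info("restricted %s: %d -> %d genes", gene_list.name, before, len(kept))
    return GeneList(name=gene_list.name, members=kept, provenance=prov)
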