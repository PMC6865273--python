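"""Essentialome construction from a gene x cell-line essentiality matrix.

A genome-wide CRISPR screen yields, per cell line, the set of genes whose
disruption kills or arrests that line (its *essentialome*).  Combining the
per-line essentialomes gives:

* the **total** essentialome — essential in at least one line (union);
* the **core** essentialome — essential in every line (intersection);
* the **majority** essentialome — essential in at least a given fraction of
  lines (default >= 95%, integer cutoff by ceiling);
* **group** essentialomes — the union within groups of lines that share a
  label, e.g. cancer type.

Scores-mode matrices are converted to binary calls with an inclusive
threshold (call = 1 iff score <= threshold); missing scores stay missing and
never count as essential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genes import GeneId

__all__ = [
    "EssentialityMatrix",
    "Essentialome",
    "call_essential",
    "per_line_essentialomes",
    "total_essentialome",
    "core_essentialome",
    "majority_essentialome",
    "group_essentialomes",
]


@dataclass(frozen=True)
class EssentialityMatrix:
    """Gene x cell-line scores or binary calls.

    ``values`` is a pandas DataFrame (rows = normalized gene symbols, columns
    = cell-line labels); NaN marks a missing measurement.  ``mode`` is
    ``"scores"`` (continuous gene-effect scores, lower = more essential) or
    ``"calls"`` (0/1).  ``line_groups``, when given, must assign every line
    exactly one group label.
    """

    values: pd.DataFrame
    mode: str = "scores"
    line_groups: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("scores", "calls"):
            raise ValueError(f"mode must be 'scores' or 'calls', got {self.mode!r}")
        if self.mode == "calls":
            vals = self.values.to_numpy(dtype=float)
            present = vals[~np.isnan(vals)]
            if present.size and not np.isin(present, (0.0, 1.0)).all():
                raise ValueError("calls-mode matrix contains values other than 0/1")
        if self.line_groups is not None:
            missing = [l for l in self.values.columns if l not in self.line_groups]
            if missing:
                raise ValueError(f"lines missing from line_groups: {missing}")

    @property
    def genes(self) -> list[GeneId]:
        return list(self.values.index)

    @property
    def lines(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Essentialome:
    """A named essential-gene set with the rule and parameters that built it."""

    name: str
    members: frozenset[GeneId]
    rule: str  # per_line | total | core | majority | group
    params: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: object) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))


def call_essential(matrix: EssentialityMatrix, threshold: float) -> EssentialityMatrix:
    """Binarize a scores matrix: call = 1 iff score <= threshold (inclusive).

    Missing scores yield missing calls.  A calls-mode matrix passes through
    unchanged (the threshold is ignored).
    """
    if matrix.mode == "calls":
        return matrix
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    calls = (matrix.values <= threshold).astype(float)
    calls = calls.where(matrix.values.notna())
    return EssentialityMatrix(values=calls, mode="calls", line_groups=matrix.line_groups)


def _require_calls(matrix: EssentialityMatrix) -> None:
    if matrix.mode != "calls":
        raise ValueError("matrix must be in calls mode; run call_essential first")


def per_line_essentialomes(calls: EssentialityMatrix) -> dict[str, Essentialome]:
    """The essential gene set of each cell line (call == 1; missing excluded)."""
    _require_calls(calls)
    out: dict[str, Essentialome] = {}
    for line in calls.values.columns:
        col = calls.values[line]
        members = frozenset(col.index[col == 1.0])
        out[line] = Essentialome(
            name=f"essentialome[{line}]", members=members, rule="per_line", params={"line": line}
        )
    return out


def total_essentialome(per_line: Mapping[str, Essentialome]) -> Essentialome:
    """Union over lines: genes essential in at least one cell line."""
    if not per_line:
        raise ValueError("need at least one per-line essentialome")
    members: frozenset[GeneId] = frozenset().union(*(e.members for e in per_line.values()))
    return Essentialome(
        name="total essentialome", members=members, rule="total", params={"n_lines": len(per_line)}
    )


def core_essentialome(per_line: Mapping[str, Essentialome]) -> Essentialome:
    """Intersection over lines: genes essential in every cell line."""
    if not per_line:
        raise ValueError("need at least one per-line essentialome")
    sets = [e.members for e in per_line.values()]
    members = frozenset(sets[0]).intersection(*sets[1:]) if len(sets) > 1 else frozenset(sets[0])
    return Essentialome(
        name="core essentialome", members=members, rule="core", params={"n_lines": len(per_line)}
    )


def majority_essentialome(per_line: Mapping[str, Essentialome], fraction: float = 0.95) -> Essentialome:
    """Genes essential in >= ceil(fraction * L) of the L cell lines.

    The ceiling makes ">= 95% of 341 lines" an integer cutoff of 324.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not per_line:
        raise ValueError("need at least one per-line essentialome")
    n_lines = len(per_line)
    cutoff = math.ceil(fraction * n_lines)
    counts: dict[GeneId, int] = {}
    for ess in per_line.values():
        for g in ess.members:
            counts[g] = counts.get(g, 0) + 1
    members = frozenset(g for g, c in counts.items() if c >= cutoff)
    return Essentialome(
        name=f"majority essentialome (>={fraction:.0%})",
        members=members,
        rule="majority",
        params={"fraction": fraction, "cutoff_lines": cutoff, "n_lines": n_lines},
    )


def group_essentialomes(
    per_line: Mapping[str, Essentialome], line_groups: Mapping[str, str]
) -> dict[str, Essentialome]:
    """Union of per-line essentialomes within each group (e.g. cancer type)."""
    missing = [l for l in per_line if l not in line_groups]
    if missing:
        raise ValueError(f"lines missing from line_groups: {missing}")
    groups: dict[str, list[str]] = {}
    for line in per_line:
        groups.setdefault(line_groups[line], []).append(line)
    out: dict[str, Essentialome] = {}
    for group, lines in groups.items():
        members: frozenset[GeneId] = frozenset().union(*(per_line[l].members for l in lines))
        out[group] = Essentialome(
            name=f"essentialome[{group}]",
            members=members,
            rule="group",
            params={"group": group, "member_lines": tuple(sorted(lines))},
        )
    return out
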