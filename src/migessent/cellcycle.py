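"""Expression across FUCCI-sorted cell-cycle stages and successive-stage DE.

FUCCI sorting yields four cell populations — early G1, late G1, S, G2/M —
each sequenced in replicate.  A gene counts as *expressed* in a stage when
its replicate-mean TPM meets an inclusive threshold (default TPM >= 1), and
is classified as not expressed / expressed in some stages / expressed
throughout.  Differential expression is tested between each successive stage
pair (early G1 -> late G1 -> S -> G2/M) with Welch's two-sample t-test on
log2(TPM + 1); a gene is "DE" if any pair is significant.  For
replicate-poor tables a fold-change-only rule is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneId, normalize_symbol

__all__ = [
    "DEFAULT_STAGES",
    "ExpressionTable",
    "ExpressionClassification",
    "read_tpm_table",
    "expressed_flags",
    "classify_expression",
    "successive_stage_de",
    "expression_report",
]

DEFAULT_STAGES: tuple[str, ...] = ("early_G1", "late_G1", "S", "G2M")


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x (stage, replicate) TPM values with an explicit stage order.

    ``tpm`` has a two-level column MultiIndex (stage, replicate); all values
    are >= 0 (NaN allowed for missing measurements).
    """

    tpm: pd.DataFrame
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not isinstance(self.tpm.columns, pd.MultiIndex) or self.tpm.columns.nlevels != 2:
            raise ValueError("tpm must have (stage, replicate) MultiIndex columns")
        present = set(self.tpm.columns.get_level_values(0))
        missing = [s for s in self.stages if s not in present]
        if missing:
            raise ValueError(f"stages with no replicate columns: {missing}")
        vals = self.tpm.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("TPM values must be non-negative")

    @property
    def genes(self) -> list[GeneId]:
        return list(self.tpm.index)

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.tpm.xs(stage, axis=1, level=0)

    def stage_means(self) -> pd.DataFrame:
        """Replicate-mean TPM per stage, columns in stage order."""
        return pd.DataFrame(
            {s: self.stage_values(s).mean(axis=1) for s in self.stages}, index=self.tpm.index
        )

    def n_replicates(self, stage: str) -> int:
        return self.stage_values(stage).shape[1]


@dataclass(frozen=True)
class ExpressionClassification:
    """Per-gene expression flags, category and successive-pair DE calls.

    ``stage_flags``: gene x stage booleans.  ``category``: per gene, one of
    not_expressed / expressed_some / expressed_all.  ``de_p``: gene x pair
    p-values (pairs labelled "early_G1->late_G1" etc.); ``de_flags``: the
    corresponding boolean calls; ``de_any``: OR over pairs.
    """

    stage_flags: pd.DataFrame
    category: pd.Series
    de_p: Optional[pd.DataFrame] = None
    de_flags: Optional[pd.DataFrame] = None

    @property
    def de_any(self) -> Optional[pd.Series]:
        return None if self.de_flags is None else self.de_flags.any(axis=1)


def read_tpm_table(
    path: str | Path, stages: Sequence[str] = DEFAULT_STAGES, sep: str = "\t"
) -> ExpressionTable:
    """Read a TPM TSV with gene rows and columns named ``<stage>.<replicate>``."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [normalize_symbol(str(g)) for g in df.index]
    cols = []
    for c in df.columns:
        stage, _, rep = str(c).rpartition(".")
        if not stage:
            raise ValueError(f"column {c!r} is not of the form <stage>.<replicate>")
        cols.append((stage, rep))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["stage", "replicate"])
    return ExpressionTable(tpm=df, stages=tuple(stages))


def expressed_flags(
    table: ExpressionTable, threshold: float = 1.0, *, per_replicate: bool = False
) -> pd.DataFrame:
    """Gene x stage booleans: expressed iff mean TPM >= threshold (inclusive).

    ``per_replicate=True`` switches to the stricter rule that every replicate
    must individually reach the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if per_replicate:
        flags = {s: (table.stage_values(s) >= threshold).all(axis=1) for s in table.stages}
    else:
        flags = {s: table.stage_values(s).mean(axis=1) >= threshold for s in table.stages}
    return pd.DataFrame(flags, index=table.tpm.index)[list(table.stages)]


def classify_expression(flags: pd.DataFrame) -> pd.Series:
    """Collapse stage flags to not_expressed / expressed_some / expressed_all."""
    n_stages = flags.shape[1]
    n_on = flags.sum(axis=1)
    out = pd.Series("expressed_some", index=flags.index, dtype=object)
    out[n_on == 0] = "not_expressed"
    out[n_on == n_stages] = "expressed_all"
    return out


def successive_stage_de(
    table: ExpressionTable,
    alpha: float = 0.05,
    method: str = "welch",
    *,
    fold_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test each successive stage pair for differential expression per gene.

    Returns ``(p_values, flags)``, both gene x pair, pairs ordered along the
    stage ladder.  ``welch`` runs Welch's t-test on log2(TPM + 1) across
    replicates and needs >= 2 replicates per stage; ``fold_change`` flags
    |log2 ratio of stage means + 1| >= log2(fold_threshold) and reports NaN
    p-values (no test).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    pairs = list(zip(table.stages[:-1], table.stages[1:]))
    pair_labels = [f"{a}->{b}" for a, b in pairs]
    if method == "welch":
        thin = [s for s in table.stages if table.n_replicates(s) < 2]
        if thin:
            raise ValueError(
                f"stages {thin} have <2 replicates; Welch's test needs replicates — "
                "use method='fold_change' instead"
            )
        pvals = {}
        for (a, b), label in zip(pairs, pair_labels):
            xa = np.log2(table.stage_values(a).to_numpy(dtype=float) + 1.0)
            xb = np.log2(table.stage_values(b).to_numpy(dtype=float) + 1.0)
            with warnings.catch_warnings():
                # identical replicates give zero variance -> NaN p, handled below
                warnings.simplefilter("ignore", RuntimeWarning)
                p = stats.ttest_ind(xa, xb, axis=1, equal_var=False).pvalue
            pvals[label] = p
        p_df = pd.DataFrame(pvals, index=table.tpm.index)[pair_labels]
        # zero-variance identical stages give NaN p; identical data is not DE
        flags = (p_df < alpha).fillna(False)
        return p_df, flags
    if method == "fold_change":
        means = table.stage_means()
        pvals = {}
        flags = {}
        for (a, b), label in zip(pairs, pair_labels):
            lfc = np.log2(means[b] + 1.0) - np.log2(means[a] + 1.0)
            flags[label] = lfc.abs() >= math.log2(fold_threshold)
            pvals[label] = pd.Series(np.nan, index=means.index)
        return (
            pd.DataFrame(pvals, index=means.index)[pair_labels],
            pd.DataFrame(flags, index=means.index)[pair_labels],
        )
    raise ValueError(f"unknown DE method {method!r}")


def expression_report(n_de: int, n_expressed: int) -> str:
    """Format the 'x of y expressed genes DE' summary with a two-decimal percent."""
    pct = 100 * n_de / n_expressed if n_expressed else float("nan")
    return f"{n_de} of {n_expressed} expressed genes DE ({pct:.2f}%)"
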