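"""Ranked differential-expression signatures from small expression matrices.

A signature is the full transcriptome ranked by a signed differential
statistic for one contrast (test group vs. adult reference): positive
scores mean higher expression in the test group. The default statistic is
a pooled-variance two-sample t with a variance floor set at the 1st
percentile of gene-wise pooled standard deviations — a light-weight
stand-in for moderated statistics that keeps low-variance genes from
dominating the ranking. A plain mean log2 difference is available as an
alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ABS_SD_FLOOR = 1e-8


class InputError(ValueError):
    """Raised when an input matrix or table violates a precondition."""


@dataclass(frozen=True)
class RankedSignature:
    """Ordered gene list with signed differential scores for one contrast.

    Entries are sorted descending by score with ties broken by gene id, so
    the ranking is fully deterministic. ``universe`` is the ordered gene
    list; ``universe_size`` equals the number of entries.
    """

    contrast_name: str
    entries: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise InputError("signature contains duplicate gene ids")

    @property
    def universe_size(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> List[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    @property
    def universe(self) -> frozenset:
        return frozenset(g for g, _ in self.entries)

    @classmethod
    def from_scores(cls, contrast_name: str, scores: pd.Series) -> "RankedSignature":
        order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(contrast_name=contrast_name, entries=tuple(order))


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of sorted row means.

    After normalization each column's sorted values equal the across-column
    mean of sorted values; within-column rank order is preserved. Ties are
    resolved by stable sort order (deterministic).
    """
    if matrix.shape[1] < 2:
        raise InputError("quantile normalization needs at least 2 columns")
    if matrix.isna().any().any():
        raise InputError("matrix contains missing values")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = target
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_to_universe(matrix: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Restrict the matrix to mapped genes and rename to target ids.

    A source gene mapped more than once keeps its first mapping (file
    order); the duplicate is logged. Rows are ordered lexicographically by
    target id.
    """
    dup = mapping.duplicated(subset="source_id", keep="first")
    if dup.any():
        logger.warning(
            "mapping table: %d duplicate source ids; first mapping wins", int(dup.sum())
        )
        mapping = mapping.loc[~dup]
    lookup = dict(zip(mapping["source_id"], mapping["target_id"]))
    keep = [g for g in matrix.index if g in lookup]
    if not keep:
        raise InputError("no genes in the matrix are covered by the mapping table")
    out = matrix.loc[keep].copy()
    out.index = pd.Index([lookup[g] for g in keep], name=matrix.index.name)
    return out.sort_index(kind="stable")


def compute_signature(
    matrix: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    test_group: str,
    reference_group: str,
    contrast_name: str | None = None,
    statistic: str = "t",
    floor_quantile: float = 0.01,
) -> RankedSignature:
    """Score every gene for the test-vs-reference contrast and rank.

    ``statistic='t'`` (default): pooled-variance two-sample t with the
    pooled SD floored at the ``floor_quantile`` quantile of gene-wise
    pooled SDs (plus a tiny absolute floor), so a gene with zero pooled
    variance and zero mean difference scores 0 rather than NaN.
    ``statistic='diff'``: plain difference of group means.
    """
    labels = pd.Series(labels, index=matrix.columns if not isinstance(labels, pd.Series) else None)
    if isinstance(labels, pd.Series) and not labels.index.equals(pd.Index(matrix.columns)):
        labels = labels.reindex(matrix.columns)
    test_cols = labels.index[labels == test_group]
    ref_cols = labels.index[labels == reference_group]
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise InputError("each group needs at least 2 samples")

    x = matrix[test_cols].to_numpy(dtype=float)
    y = matrix[ref_cols].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    diff = x.mean(axis=1) - y.mean(axis=1)

    if statistic == "diff":
        scores = diff
    elif statistic == "t":
        ss1 = x.var(axis=1, ddof=1) * (n1 - 1)
        ss2 = y.var(axis=1, ddof=1) * (n2 - 1)
        pooled_sd = np.sqrt((ss1 + ss2) / (n1 + n2 - 2))
        floor = max(float(np.quantile(pooled_sd, floor_quantile)), _ABS_SD_FLOOR)
        sd = np.maximum(pooled_sd, floor)
        scores = diff / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    else:
        raise InputError(f"unknown statistic {statistic!r}; use 't' or 'diff'")

    name = contrast_name or f"{test_group}_vs_{reference_group}"
    return RankedSignature.from_scores(name, pd.Series(scores, index=matrix.index))
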