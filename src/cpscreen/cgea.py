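"""Chemogenomic enrichment analysis (CGEA).

Two levels. Level one: every chemical up-signature is tested against every
pathway gene set with a one-sided Fisher exact test on the 2x2 overlap
table over the signature universe; the full chemicals-by-pathways P matrix
is Benjamini-Hochberg corrected globally (one correction per pathway
library) and binarized at adjusted significance. Level two: per pathway, a
one-sided hypergeometric test asks whether the chemicals enriched for that
pathway are overrepresented among the candidate disruptors relative to the
whole library, again BH-corrected across pathways.

The one-sided Fisher P of a 2x2 table with fixed margins equals the
hypergeometric upper tail, which is what the vectorized implementation
computes cell-wise (scipy's ``hypergeom.sf``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ChemicalLibrary
from .signatures import InputError

logger = logging.getLogger(__name__)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order.

    Sort ascending, multiply by m/rank, enforce monotonicity from the
    largest P down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class EnrichmentMatrix:
    """Chemicals-by-pathways Fisher enrichment with global BH correction."""

    p: pd.DataFrame
    padj: pd.DataFrame
    binary: pd.DataFrame
    alpha: float
    n_tests: int
    universe_size: int
    dropped_pathways: List[str] = field(default_factory=list)

    @property
    def chemicals(self) -> List[str]:
        return list(self.p.index)

    @property
    def pathways(self) -> List[str]:
        return list(self.p.columns)


def expected_test_count(n_chemicals: int, n_pathways: int) -> int:
    """Bookkeeping: number of pairwise enrichment tests for a run."""
    return int(n_chemicals) * int(n_pathways)


def pairwise_enrichment(
    chem_up: ChemicalLibrary,
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    bh_scope: str = "global",
) -> EnrichmentMatrix:
    """Fisher enrichment of every chemical set against every pathway set.

    Pathway sets are intersected with the universe first; pathways left
    empty are dropped (logged). BH is computed across all cells of the
    matrix by default, or per chemical row with ``bh_scope='per_chemical'``.
    """
    universe = sorted(set(universe))
    n_univ = len(universe)
    if n_univ == 0:
        raise InputError("empty universe")
    gene_index = {g: i for i, g in enumerate(universe)}

    chem_ids = sorted(chem_up.sets)
    chem_mat = np.zeros((len(chem_ids), n_univ), dtype=bool)
    for i, c in enumerate(chem_ids):
        idx = [gene_index[g] for g in chem_up.sets[c] if g in gene_index]
        chem_mat[i, idx] = True

    path_ids: List[str] = []
    dropped: List[str] = []
    rows = []
    for p_id in sorted(pathways):
        idx = [gene_index[g] for g in set(pathways[p_id]) if g in gene_index]
        if not idx:
            dropped.append(p_id)
            continue
        row = np.zeros(n_univ, dtype=bool)
        row[idx] = True
        path_ids.append(p_id)
        rows.append(row)
    if dropped:
        logger.info("dropped %d pathways with no universe overlap", len(dropped))
    if not path_ids:
        raise InputError("no pathway intersects the universe")
    path_mat = np.stack(rows)

    overlap = chem_mat.astype(np.int64) @ path_mat.T.astype(np.int64)
    chem_sizes = chem_mat.sum(axis=1)[:, None]
    path_sizes = path_mat.sum(axis=1)[None, :]
    # One-sided Fisher P = hypergeometric upper tail P(X >= overlap).
    pvals = stats.hypergeom.sf(overlap - 1, n_univ, path_sizes, chem_sizes)
    pvals = np.clip(pvals, 0.0, 1.0)

    if bh_scope == "global":
        padj = bh_adjust(pvals.ravel()).reshape(pvals.shape)
    elif bh_scope == "per_chemical":
        padj = np.vstack([bh_adjust(row) for row in pvals])
    else:
        raise InputError("bh_scope must be 'global' or 'per_chemical'")

    p_df = pd.DataFrame(pvals, index=chem_ids, columns=path_ids)
    padj_df = pd.DataFrame(padj, index=chem_ids, columns=path_ids)
    binary_df = (padj_df < alpha).astype(int)
    return EnrichmentMatrix(
        p=p_df,
        padj=padj_df,
        binary=binary_df,
        alpha=alpha,
        n_tests=expected_test_count(len(chem_ids), len(path_ids)),
        universe_size=n_univ,
        dropped_pathways=dropped,
    )


@dataclass(frozen=True)
class CgeaResult:
    pathway_id: str
    n_enriched_total: int
    n_enriched_in_candidates: int
    hyper_p: float
    padj: float
    flagged: bool = False     # no chemical enriched; P = 1 by convention


def pathway_overrepresentation(
    matrix: EnrichmentMatrix,
    candidates: Iterable[str],
) -> List[CgeaResult]:
    """Per pathway: are enriched chemicals overrepresented among candidates?

    X ~ Hypergeometric(N = all chemicals, K = candidates, n = chemicals
    enriched for the pathway); hyper_p = P(X >= observed candidate
    enrichments), BH-adjusted across pathways.
    """
    candidates = frozenset(candidates)
    chem_ids = matrix.chemicals
    if not candidates <= set(chem_ids):
        raise InputError("candidates must be a subset of the matrix rows")
    n_total = len(chem_ids)
    k_cand = len(candidates)
    cand_mask = np.array([c in candidates for c in chem_ids])

    binary = matrix.binary.to_numpy()
    n_enriched = binary.sum(axis=0)
    x_in_cand = binary[cand_mask].sum(axis=0)

    pvals = np.ones(len(matrix.pathways))
    nonzero = n_enriched > 0
    pvals[nonzero] = stats.hypergeom.sf(
        x_in_cand[nonzero] - 1, n_total, k_cand, n_enriched[nonzero]
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    padj = bh_adjust(pvals)

    return [
        CgeaResult(
            pathway_id=p_id,
            n_enriched_total=int(n_enriched[j]),
            n_enriched_in_candidates=int(x_in_cand[j]),
            hyper_p=float(pvals[j]),
            padj=float(padj[j]),
            flagged=not bool(nonzero[j]),
        )
        for j, p_id in enumerate(matrix.pathways)
    ]


def select_pathways(
    results: Iterable[CgeaResult], alpha: float = 0.05
) -> FrozenSet[str]:
    return frozenset(r.pathway_id for r in results if r.padj < alpha)
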