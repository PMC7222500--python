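"""Gene Set Enrichment Analysis with a random-set permutation null.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running-sum statistic over a ranked gene list: walking down the ranking,
genes in the set add ``|score|^w / sum_hits |score|^w`` and genes outside
subtract ``1/(N - n_hits)``; the ES is the running-sum value of maximum
absolute deviation, carrying its sign. A positive ES concentrates the set
at the top of the ranking (genes up in the test group), a negative ES at
the bottom.

The null is built by gene-set permutation: ES values of uniformly sampled
gene sets of the same size. With n = 3 samples per group, phenotype
permutation is not viable, and the random-set null also gives the FDR its
set-size control: the nominal P is the add-one-corrected same-sign tail of
the size-matched null; NES divides the ES by the mean |null ES| of the
same sign; and the FDR q compares, separately per sign, the tail fraction
of the pooled null NES distribution with the tail fraction of observed
NES, clipped to [0, 1]. Chemicals with identical set sizes share one null
batch, and each batch's RNG stream is derived from (seed, set size), so
results are independent of scoring order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ChemicalLibrary
from .signatures import InputError, RankedSignature


@dataclass(frozen=True)
class GseaResult:
    chemical_id: str
    set_size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float


def _weights(scores: np.ndarray, weight_exponent: float) -> np.ndarray:
    return np.abs(scores) ** weight_exponent


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Vectorized ES for rows of sorted hit positions (0-based ranks).

    Extrema of the running sum occur immediately after a hit (candidate
    maxima) or immediately before a hit (candidate minima); the ES is the
    candidate of largest absolute value, positive on ties.
    """
    n_univ = len(weights)
    pos = np.atleast_2d(positions)
    k = pos.shape[1]
    if k >= n_univ:
        raise InputError("gene set must be a proper subset of the universe")
    hit_w = weights[pos]
    cum_w = np.cumsum(hit_w, axis=1)
    total = cum_w[:, -1]
    zero = total <= 0.0
    if np.any(zero):
        # All hit weights zero (all-zero scores): fall back to unweighted.
        uniform = np.arange(1, k + 1, dtype=float)
        cum_w = np.where(zero[:, None], uniform[None, :], cum_w)
        hit_w = np.where(zero[:, None], 1.0, hit_w)
        total = np.where(zero, float(k), total)
    miss = 1.0 / (n_univ - k)
    j = np.arange(1, k + 1, dtype=float)
    after = cum_w / total[:, None] - (pos + 1 - j[None, :]) * miss
    before = (cum_w - hit_w) / total[:, None] - (pos - (j[None, :] - 1)) * miss
    mx = after.max(axis=1)
    mn = before.min(axis=1)
    # Positive-on-tie, with a tolerance: exact |max| == |min| ties occur
    # generically (miss-step symmetry) and float jitter must not flip them.
    return np.where(np.abs(mx) >= np.abs(mn) - 1e-12, mx, mn)


def enrichment_score(
    ranked: RankedSignature,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> Tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    The running sum is computed by direct accumulation over the ranking;
    the returned ES is its value of maximum absolute deviation (sign
    preserved, positive on exact ties).
    """
    genes = ranked.genes
    index = {g: i for i, g in enumerate(genes)}
    hits = sorted(index[g] for g in set(gene_set) if g in index)
    n = len(genes)
    if not hits:
        raise InputError("gene set does not intersect the signature universe")
    if len(hits) == n:
        raise InputError("gene set equals the universe; miss penalty undefined")

    weights = _weights(ranked.scores, weight_exponent)
    hit_w = weights[hits]
    total = hit_w.sum()
    if total <= 0.0:
        hit_w = np.ones_like(hit_w)
        total = float(len(hits))
    increments = np.full(n, -1.0 / (n - len(hits)))
    increments[hits] = hit_w / total
    running = np.cumsum(increments)
    mx, mn = float(running.max()), float(running.min())
    # Maximum absolute deviation, positive on (near-)ties — matches the
    # vectorized batch path's tolerance rule.
    es = mx if abs(mx) >= abs(mn) - 1e-12 else mn
    return es, running


def permutation_null(
    ranked: RankedSignature,
    set_size: int,
    n_perm: int,
    seed: int | Sequence[int],
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Null ES values for uniformly sampled gene sets of ``set_size``."""
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    n = ranked.universe_size
    if set_size >= n:
        raise InputError("set_size must be smaller than the universe")
    if set_size < 1:
        raise InputError("set_size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_perm, n))
    pos = np.argpartition(draws, set_size, axis=1)[:, :set_size]
    pos.sort(axis=1)
    weights = _weights(ranked.scores, weight_exponent)
    return _es_from_positions(pos, weights)


def _p_nominal(es: float, null: np.ndarray) -> float:
    if es > 0:
        pool = null[null > 0]
        count = int(np.sum(pool >= es))
    elif es < 0:
        pool = null[null < 0]
        count = int(np.sum(pool <= es))
    else:
        return 1.0
    return (1 + count) / (1 + len(pool))


def _nes(es: float, null: np.ndarray) -> float:
    if es > 0:
        pool = null[null > 0]
    elif es < 0:
        pool = null[null < 0]
    else:
        return 0.0
    if len(pool) == 0:
        return 0.0
    return es / float(np.mean(np.abs(pool)))


def _null_nes(null: np.ndarray) -> np.ndarray:
    """Normalize each null ES by the same-sign mean within its batch."""
    out = np.zeros_like(null)
    pos = null > 0
    neg = null < 0
    if pos.any():
        out[pos] = null[pos] / np.mean(null[pos])
    if neg.any():
        out[neg] = null[neg] / np.mean(np.abs(null[neg]))
    return out


def fdr_from_nes(observed_nes: np.ndarray, pooled_null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q per observed NES, signs handled as separate pools.

    q = (fraction of same-sign pooled null NES at least as extreme) /
        (fraction of same-sign observed NES at least as extreme), clipped
    to [0, 1]. Zero NES values get q = 1.
    """
    obs = np.asarray(observed_nes, dtype=float)
    null = np.asarray(pooled_null_nes, dtype=float)
    q = np.ones_like(obs)
    for sign in (1, -1):
        mask = obs > 0 if sign == 1 else obs < 0
        if not mask.any():
            continue
        null_pool = null[null > 0] if sign == 1 else null[null < 0]
        obs_pool = obs[mask]
        n_null = len(null_pool)
        n_obs = len(obs_pool)
        for i in np.flatnonzero(mask):
            v = obs[i]
            if sign == 1:
                frac_null = np.sum(null_pool >= v) / n_null if n_null else 1.0
                frac_obs = np.sum(obs_pool >= v) / n_obs
            else:
                frac_null = np.sum(null_pool <= v) / n_null if n_null else 1.0
                frac_obs = np.sum(obs_pool <= v) / n_obs
            q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
    return q


def score_library(
    signature: RankedSignature,
    library: ChemicalLibrary,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    keep_null: bool = False,
) -> List[GseaResult] | Tuple[List[GseaResult], Dict[int, np.ndarray]]:
    """Score every chemical set in the library against the signature.

    Chemicals of identical set size share one null batch seeded by
    (seed, set size); the pooled null NES for the FDR replicates each
    batch once per chemical of that size so the null pool mirrors the
    observed set-size distribution. Chemicals whose sets cannot be scored
    (no universe overlap) are skipped.
    """
    if not library.universe <= signature.universe:
        raise InputError("library universe must be contained in the signature universe")

    index = {g: i for i, g in enumerate(signature.genes)}
    weights = _weights(signature.scores, weight_exponent)

    chem_ids: List[str] = []
    positions: Dict[str, np.ndarray] = {}
    for chem in sorted(library.sets):
        hits = sorted(index[g] for g in library.sets[chem] if g in index)
        if not hits or len(hits) >= signature.universe_size:
            continue
        chem_ids.append(chem)
        positions[chem] = np.array(hits)

    sizes = {c: len(positions[c]) for c in chem_ids}
    nulls: Dict[int, np.ndarray] = {}
    for size in sorted(set(sizes.values())):
        nulls[size] = permutation_null(
            signature, size, n_perm, seed=[seed, size],
            weight_exponent=weight_exponent,
        )

    es_obs = np.array(
        [
            float(_es_from_positions(positions[c][None, :], weights)[0])
            for c in chem_ids
        ]
    )
    nes_obs = np.array([_nes(es_obs[i], nulls[sizes[c]]) for i, c in enumerate(chem_ids)])
    p_nom = np.array([_p_nominal(es_obs[i], nulls[sizes[c]]) for i, c in enumerate(chem_ids)])

    pooled = (
        np.concatenate([_null_nes(nulls[sizes[c]]) for c in chem_ids])
        if chem_ids
        else np.array([])
    )
    q = fdr_from_nes(nes_obs, pooled)

    results = [
        GseaResult(
            chemical_id=c,
            set_size=sizes[c],
            es=float(es_obs[i]),
            nes=float(nes_obs[i]),
            p_nominal=float(p_nom[i]),
            fdr_q=float(q[i]),
        )
        for i, c in enumerate(chem_ids)
    ]
    if keep_null:
        return results, nulls
    return results


def select_significant(
    results: Iterable[GseaResult],
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.25,
    sign_filter: Optional[str] = None,
) -> frozenset:
    """Chemical ids passing the screening thresholds.

    ``sign_filter`` of "negative"/"positive" additionally requires the ES
    sign to match (a negative ES means the chemical's genes sit among the
    genes downregulated in the contrast).
    """
    if sign_filter not in (None, "negative", "positive"):
        raise ValueError("sign_filter must be None, 'negative' or 'positive'")
    keep = []
    for r in results:
        if not (r.p_nominal < p_threshold and r.fdr_q < fdr_threshold):
            continue
        if sign_filter == "negative" and not r.es < 0:
            continue
        if sign_filter == "positive" and not r.es > 0:
            continue
        keep.append(r.chemical_id)
    return frozenset(keep)


def results_to_rows(results: Iterable[GseaResult]) -> List[dict]:
    return [
        {
            "chemical_id": r.chemical_id,
            "set_size": r.set_size,
            "es": r.es,
            "nes": r.nes,
            "p_nominal": r.p_nominal,
            "fdr_q": r.fdr_q,
        }
        for r in results
    ]
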