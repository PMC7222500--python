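"""Direction-bias tests and candidate intersection across signatures.

After scoring the chemical libraries against both plasticity contrasts,
the screen asks (1) whether significant composite matches skew toward
negative enrichment scores (chemicals hitting genes downregulated during
the critical period), (2) whether, among the directional libraries,
up-signatures dominate the significant negative matches, and (3) which
chemicals from the up library are significant with negative scores in
*both* contrasts — the candidate disruptors — together with a Fisher
exact test of that overlap against chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Set

import numpy as np
from scipy import stats

from .gsea import GseaResult


class TestError(ValueError):
    """Raised when a statistical test is undefined for the given input."""


@dataclass(frozen=True)
class BinomialResult:
    """Exact two-sided binomial test (minimum-likelihood two-sidedness)."""

    k: int
    n: int
    p0: float
    p_value: float

    @property
    def proportion(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap table with cross-product odds ratio and Fisher P."""

    a: int                 # |A and B|
    b: int                 # |A \ B|
    c: int                 # |B \ A|
    d: int                 # neither
    odds_ratio: float      # a*d / (b*c); inf sentinel when b*c == 0 < a*d
    or_infinite: bool
    p_value: float         # one-sided (greater) Fisher exact


def binomial_test(k: int, n: int, p0: float) -> BinomialResult:
    if n <= 0:
        raise TestError("binomial test undefined for n = 0")
    if not 0 <= k <= n:
        raise TestError("k must satisfy 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise TestError(f"null proportion must lie strictly in (0, 1), got {p0}")
    p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    return BinomialResult(k=k, n=n, p0=p0, p_value=float(min(p, 1.0)))


def direction_bias_test(composite_results: Iterable[GseaResult]) -> BinomialResult:
    """Do significant composite matches skew toward negative ES?

    k = number of negative-ES chemicals among the supplied (significant)
    results, n = total, null proportion 0.5.
    """
    results = list(composite_results)
    if not results:
        raise TestError("direction bias test undefined on an empty result set")
    k = sum(1 for r in results if r.es < 0)
    return binomial_test(k, len(results), 0.5)


def updown_bias_test(
    up_significant: Set[str] | FrozenSet[str],
    down_significant: Set[str] | FrozenSet[str],
    n_up_library: int,
    n_down_library: int,
    null: str = "library",
) -> BinomialResult:
    """Among significant directional matches, does the up library dominate?

    k = |up significant|, n = k + |down significant|. The default null
    proportion is the library-size share n_up/(n_up + n_down); ``null=
    'half'`` uses 0.5 instead.
    """
    k = len(up_significant)
    n = k + len(down_significant)
    if n == 0:
        raise TestError("up/down bias test undefined with no significant matches")
    if null == "library":
        if n_up_library <= 0 or n_down_library <= 0:
            raise TestError("library sizes must be positive for the library null")
        p0 = n_up_library / (n_up_library + n_down_library)
    elif null == "half":
        p0 = 0.5
    else:
        raise TestError("null must be 'library' or 'half'")
    return binomial_test(k, n, p0)


def intersect_candidates(
    sig_a: Iterable[str], sig_b: Iterable[str]
) -> FrozenSet[str]:
    """Chemicals significant in both signatures."""
    return frozenset(sig_a) & frozenset(sig_b)


def overlap_odds(
    set_a: Iterable[str], set_b: Iterable[str], n_total: int
) -> OverlapResult:
    """Fisher exact test (one-sided, greater) of the overlap of two sets."""
    sa, sb = frozenset(set_a), frozenset(set_b)
    union = sa | sb
    if n_total < len(union):
        raise TestError(
            f"n_total={n_total} smaller than the union size {len(union)}"
        )
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = n_total - len(union)
    p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    if b * c == 0:
        infinite = a * d > 0
        oddsr = np.inf if infinite else np.nan
    else:
        oddsr = (a * d) / (b * c)
        infinite = False
    return OverlapResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(oddsr),
        or_infinite=bool(infinite),
        p_value=float(p),
    )


def candidate_screen(
    up_results_a: Iterable[GseaResult],
    up_results_b: Iterable[GseaResult],
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.25,
) -> dict:
    """Convenience wrapper: negative-score screen in both contrasts.

    Returns the per-contrast significant sets, their intersection, and the
    Fisher overlap statistics over the scored up-library.
    """
    from .gsea import select_significant

    results_a = list(up_results_a)
    results_b = list(up_results_b)
    sig_a = select_significant(results_a, p_threshold, fdr_threshold, "negative")
    sig_b = select_significant(results_b, p_threshold, fdr_threshold, "negative")
    scored = {r.chemical_id for r in results_a} | {r.chemical_id for r in results_b}
    candidates = intersect_candidates(sig_a, sig_b)
    overlap = overlap_odds(sig_a, sig_b, len(scored)) if sig_a or sig_b else None
    return {
        "significant_a": sig_a,
        "significant_b": sig_b,
        "candidates": candidates,
        "overlap": overlap,
    }
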