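"""Enrichment-score mechanics, permutation null, NES/FDR bookkeeping.

Oracles here are deliberately naive: a step-by-step running-sum loop and
exhaustive enumeration of all subsets of tiny universes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpscreen import (
    RankedSignature,
    enrichment_score,
    permutation_null,
    score_library,
    select_significant,
)
from cpscreen.chem import ChemicalLibrary
from cpscreen.gsea import GseaResult, _es_from_positions, _null_nes, fdr_from_nes
from cpscreen.signatures import InputError


def brute_force_es(scores, hit_mask, weight=1.0):
    """Independent running-sum oracle: explicit loop, no vectorization."""
    n = len(scores)
    n_hit = int(np.sum(hit_mask))
    w = [abs(s) ** weight for s in scores]
    total = sum(w[i] for i in range(n) if hit_mask[i])
    if total == 0:
        w = [1.0] * n
        total = float(n_hit)
    running, cur = [], 0.0
    for i in range(n):
        cur += w[i] / total if hit_mask[i] else -1.0 / (n - n_hit)
        running.append(cur)
    mx, mn = max(running), min(running)
    # Positive on (near-)ties: exact |max| == |min| ties arise from the
    # miss-step symmetry and must resolve identically across code paths.
    return mx if abs(mx) >= abs(mn) - 1e-12 else mn


def _sig(scores):
    genes = [f"g{i:02d}" for i in range(len(scores))]
    entries = tuple(sorted(zip(genes, map(float, scores)),
                           key=lambda kv: (-kv[1], kv[0])))
    return RankedSignature("test", entries)


@pytest.mark.parametrize(
    "gene_set, weight, expected",
    [({"a"}, 1.0, 1.0), ({"d"}, 1.0, -1.0), ({"a", "c"}, 0.0, 0.5)],
)
def test_enrichment_score_hand_stepped_examples(toy_signature, gene_set, weight, expected):
    es, running = enrichment_score(toy_signature, gene_set, weight_exponent=weight)
    assert es == pytest.approx(expected)
    assert len(running) == 4
    assert running[-1] == pytest.approx(0.0, abs=1e-12)


def test_enrichment_score_running_sum_for_bottom_hit(toy_signature):
    _, running = enrichment_score(toy_signature, {"d"})
    assert np.allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0])


def test_enrichment_score_rejects_degenerate_sets(toy_signature):
    with pytest.raises(InputError):
        enrichment_score(toy_signature, {"z1", "z2"})
    with pytest.raises(InputError):
        enrichment_score(toy_signature, {"a", "b", "c", "d"})


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.data())
def test_es_bounded_and_batch_path_matches_loop_oracle(data):
    n = data.draw(st.integers(4, 12))
    scores = data.draw(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
    )
    scores = sorted(scores, reverse=True)
    k = data.draw(st.integers(1, n - 1))
    hits = data.draw(st.permutations(range(n))).copy()[:k]
    mask = np.zeros(n, dtype=bool)
    mask[hits] = True

    oracle = brute_force_es(scores, mask)
    weights = np.abs(np.array(scores, dtype=float))
    batch = float(_es_from_positions(np.sort(np.array(hits))[None, :], weights)[0])
    sig = _sig(scores)
    direct, _ = enrichment_score(sig, {sig.genes[i] for i in np.flatnonzero(mask)})
    assert -1.0 <= batch <= 1.0
    assert batch == pytest.approx(oracle, abs=1e-12)
    assert direct == pytest.approx(oracle, abs=1e-12)


def test_unweighted_es_invariant_to_monotone_score_rescaling():
    rng = np.random.default_rng(2)
    scores = np.sort(rng.normal(size=10))[::-1]
    sig1 = _sig(scores)
    sig2 = _sig(3.0 * scores + np.linspace(0.5, 0.0, 10))  # order-preserving
    gene_set = {"g01", "g04", "g07"}
    es1, _ = enrichment_score(sig1, gene_set, weight_exponent=0.0)
    es2, _ = enrichment_score(sig2, gene_set, weight_exponent=0.0)
    assert es1 == pytest.approx(es2)


def test_permutation_null_deterministic_and_guarded(toy_signature):
    a = permutation_null(toy_signature, 2, 50, seed=9)
    b = permutation_null(toy_signature, 2, 50, seed=9)
    assert np.array_equal(a, b)
    with pytest.raises(InputError):
        permutation_null(toy_signature, 2, 0, seed=9)
    with pytest.raises(InputError):
        permutation_null(toy_signature, 4, 10, seed=9)


def test_sampled_null_matches_exhaustive_enumeration():
    """Universe of 5 genes, sets of size 2: the sampled null reproduces the
    enumeration over all C(5,2)=10 subsets within Monte-Carlo tolerance."""
    scores = [2.5, 1.4, 0.8, -0.6, -1.9]
    sig = _sig(scores)
    exact = []
    for combo in combinations(range(5), 2):
        mask = np.zeros(5, dtype=bool)
        mask[list(combo)] = True
        exact.append(brute_force_es(sig.scores, mask))
    exact = np.sort(exact)

    null = permutation_null(sig, 2, 10_000, seed=4)
    # Every sampled value is one of the 10 enumerated values...
    assert set(np.round(null, 10)) <= set(np.round(exact, 10))
    # ...and each enumerated value appears with frequency 1/10 +- 3 MC SE.
    se = np.sqrt(0.1 * 0.9 / 10_000)
    for value in np.unique(np.round(exact, 10)):
        freq = np.mean(np.round(null, 10) == value)
        expected = np.mean(np.round(exact, 10) == value)
        assert abs(freq - expected) < 3 * se + 1e-12


def _library(sets, universe):
    return ChemicalLibrary("up", {c: frozenset(s) for c, s in sets.items()},
                           frozenset(universe))


def test_top_set_scores_extreme_with_minimal_p():
    rng = np.random.default_rng(0)
    scores = np.sort(rng.normal(size=50))[::-1]
    sig = _sig(scores)
    top = set(sig.genes[:5])
    lib = _library({"top": top, "copy": set(top)}, sig.universe)
    results, nulls = score_library(sig, lib, n_perm=200, seed=1, keep_null=True)
    by_id = {r.chemical_id: r for r in results}
    assert by_id["top"].es > 0.9
    # No sampled null set beats the literal top-5 set: the add-one P is at
    # its floor, 1 / (1 + number of positive nulls).
    n_pos = int(np.sum(nulls[5] > 0))
    assert by_id["top"].p_nominal == pytest.approx(1 / (1 + n_pos))
    assert by_id["top"].p_nominal >= 1 / 201
    # Identical sets give identical rows.
    assert by_id["top"].es == by_id["copy"].es
    assert by_id["top"].fdr_q == by_id["copy"].fdr_q


def test_fdr_q_matches_independent_recomputation_from_null_arrays():
    rng = np.random.default_rng(7)
    scores = np.sort(rng.normal(size=50))[::-1]
    sig = _sig(scores)
    sets = {
        f"c{i}": set(rng.choice(sig.genes, size=size, replace=False))
        for i, size in enumerate([5, 5, 8, 8, 8, 12, 12, 15, 15, 20])
    }
    lib = _library(sets, sig.universe)
    results, nulls = score_library(sig, lib, n_perm=200, seed=7, keep_null=True)

    # Re-derive every q from the saved null arrays with plain loops.
    obs_nes = {r.chemical_id: r.nes for r in results}
    pooled = []
    for r in results:
        pooled.extend(_null_nes(nulls[r.set_size]).tolist())
    pooled = np.array(pooled)
    nes_values = np.array([obs_nes[r.chemical_id] for r in results])
    for r in results:
        v = obs_nes[r.chemical_id]
        if v > 0:
            frac_null = np.mean(pooled[pooled > 0] >= v)
            frac_obs = np.mean(nes_values[nes_values > 0] >= v)
        elif v < 0:
            frac_null = np.mean(pooled[pooled < 0] <= v)
            frac_obs = np.mean(nes_values[nes_values < 0] <= v)
        else:
            continue
        expected = min(1.0, frac_null / frac_obs)
        assert r.fdr_q == pytest.approx(expected, abs=1e-12)


def test_p_nominal_uses_addone_same_sign_tail():
    rng = np.random.default_rng(5)
    scores = np.sort(rng.normal(size=30))[::-1]
    sig = _sig(scores)
    sets = {"c": set(rng.choice(sig.genes, size=6, replace=False))}
    results, nulls = score_library(sig, _library(sets, sig.universe),
                                   n_perm=500, seed=3, keep_null=True)
    r = results[0]
    null = nulls[6]
    pool = null[null > 0] if r.es > 0 else null[null < 0]
    extreme = np.sum(pool >= r.es) if r.es > 0 else np.sum(pool <= r.es)
    assert r.p_nominal == pytest.approx((1 + extreme) / (1 + len(pool)))
    assert r.p_nominal >= 1 / 501
    assert np.sign(r.nes) == np.sign(r.es)


def test_select_significant_threshold_and_sign_logic():
    def row(chem, es, p, q):
        return GseaResult(chem, 10, es, es * 1.5, p, q)

    results = [
        row("excluded_q", -0.5, 0.04, 0.30),
        row("included", -0.5, 0.04, 0.20),
        row("wrong_sign", 0.5, 0.01, 0.01),
        row("excluded_p", -0.5, 0.06, 0.01),
    ]
    assert select_significant(results, sign_filter="negative") == {"included"}
    assert select_significant(results) == {"included", "wrong_sign"}
    assert select_significant([]) == frozenset()


def test_exhaustive_p_matches_sampled_p_on_tiny_universe():
    """For a 6-gene universe the nominal P from the sampled null agrees
    with exhaustive enumeration of all same-size subsets within 3 MC SE."""
    scores = [1.8, 1.1, 0.4, -0.2, -0.9, -1.7]
    sig = _sig(scores)
    gene_set = {sig.genes[4], sig.genes[5]}
    es, _ = enrichment_score(sig, gene_set)

    exact_null = []
    for combo in combinations(range(6), 2):
        mask = np.zeros(6, dtype=bool)
        mask[list(combo)] = True
        exact_null.append(brute_force_es(sig.scores, mask))
    exact_null = np.array(exact_null)
    pool = exact_null[exact_null < 0]
    # Limit of the same-sign permutation tail: conditional tail fraction
    # over the enumerated subsets.
    p_exact = np.sum(pool <= es) / len(pool)

    null = permutation_null(sig, 2, 4000, seed=11)
    pool_s = null[null < 0]
    p_sampled = np.sum(pool_s <= es) / len(pool_s)
    se = np.sqrt(p_exact * (1 - p_exact) / len(pool_s))
    assert abs(p_sampled - p_exact) <= 3 * se + 1e-3
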