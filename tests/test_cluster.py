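"""Feature construction, Ward clustering, exposure and microglia scans."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from cpscreen import (
    build_feature_matrix,
    exposure_enrichment,
    hierarchical_cluster,
    microglia_scan,
)
from cpscreen.cgea import EnrichmentMatrix
from cpscreen.cluster import ClusterAssignment
from cpscreen.signatures import InputError


def _enrichment_matrix(padj, chems, paths):
    df = pd.DataFrame(padj, index=chems, columns=paths)
    return EnrichmentMatrix(p=df, padj=df, binary=(df < 0.05).astype(int),
                            alpha=0.05, n_tests=df.size, universe_size=100)


def test_feature_matrix_values_floor_and_zero():
    chems, paths = ["c1", "c2"], ["p1", "p2"]
    padj = [[0.05, 1.0], [0.0, 0.5]]
    matrix = _enrichment_matrix(padj, chems, paths)
    feats = build_feature_matrix(matrix, chems, paths)
    assert feats.loc["c1", "p1"] == pytest.approx(-np.log10(0.05))
    assert feats.loc["c1", "p2"] == 0.0
    assert feats.loc["c2", "p1"] == pytest.approx(300.0)   # underflow floored
    assert np.isfinite(feats.to_numpy()).all()
    with pytest.raises(InputError):
        build_feature_matrix(matrix, chems, [])


def _blobs(n_per=10, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per, 4)),
        rng.normal(sep, 1.0, size=(n_per, 4)),
    ])
    ids = [f"c{i:02d}" for i in range(2 * n_per)]
    return pd.DataFrame(x, index=ids), ids


@pytest.mark.parametrize("linkage", ["ward_d", "ward_d2"])
def test_separated_blobs_recovered_perfectly(linkage):
    from sklearn.metrics import adjusted_rand_score

    feats, ids = _blobs()
    out = hierarchical_cluster(feats, k=2, linkage=linkage)
    truth = [0] * 10 + [1] * 10
    assert adjusted_rand_score(truth, [out.labels[c] for c in ids]) == 1.0
    # Density labeling: the high-mean blob is "B".
    assert {out.labels[c] for c in ids[10:]} == {"B"}


def test_duplicated_rows_co_cluster_and_k_edge_cases():
    base = pd.DataFrame(
        [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]],
        index=["a1", "a2", "b1", "b2"],
    )
    dup = pd.concat([base, base.set_axis(["a3", "a4", "b3", "b4"])])
    out = hierarchical_cluster(dup, k=2)
    assert out.labels["a1"] == out.labels["a3"]
    assert out.labels["b1"] == out.labels["b3"]

    single = hierarchical_cluster(base, k=1)
    assert set(single.labels.values()) == {"A"}
    with pytest.raises(InputError):
        hierarchical_cluster(base, k=5)


def test_clustering_invariant_to_row_permutation():
    feats, ids = _blobs(n_per=8, sep=6.0, seed=3)
    out1 = hierarchical_cluster(feats, k=2)
    shuffled = feats.sample(frac=1.0, random_state=9)
    out2 = hierarchical_cluster(shuffled, k=2)
    partition1 = {frozenset(out1.members(l)) for l in out1.cluster_names}
    partition2 = {frozenset(out2.members(l)) for l in out2.cluster_names}
    assert partition1 == partition2


def _assignment(n_a=29, n_b=21):
    labels = {f"a{i}": "A" for i in range(n_a)}
    labels.update({f"b{i}": "B" for i in range(n_b)})
    return ClusterAssignment(labels, "ward_d", 2)


def test_exposure_fold_reproduces_printed_counts():
    """15/21 medium-high in B vs 10/29 in A gives the 2.07-fold enrichment."""
    assignment = _assignment()
    annotations = {}
    for i in range(29):
        annotations[f"a{i}"] = "medium" if i < 10 else "low"
    for i in range(21):
        annotations[f"b{i}"] = "high" if i < 15 else "low"
    out = exposure_enrichment(assignment, annotations)
    assert out.fold == pytest.approx((15 / 21) / (10 / 29))
    assert round(out.fold, 2) == 2.07
    assert out.binomial_split.k == 15 and out.binomial_split.n == 25
    assert out.binomial_split.p0 == pytest.approx(21 / 50)
    assert out.binomial_split.p_value == pytest.approx(0.103, abs=5e-4)


def test_exposure_fold_unity_reciprocal_and_flagging():
    assignment = _assignment(10, 10)
    annotations = {f"a{i}": ("high" if i < 4 else "low") for i in range(10)}
    annotations.update({f"b{i}": ("medium" if i < 4 else "low") for i in range(10)})
    assert exposure_enrichment(assignment, annotations).fold == pytest.approx(1.0)

    biased = {f"a{i}": ("high" if i < 2 else "low") for i in range(10)}
    biased.update({f"b{i}": ("medium" if i < 8 else "low") for i in range(10)})
    fold = exposure_enrichment(_assignment(10, 10), biased).fold
    swapped = ClusterAssignment(
        {c: ("A" if l == "B" else "B")
         for c, l in _assignment(10, 10).labels.items()},
        "ward_d", 2,
    )
    fold_swapped = exposure_enrichment(swapped, biased).fold
    assert fold_swapped == pytest.approx(1.0 / fold)

    none_annotated_mh = {f"a{i}": "low" for i in range(10)}
    none_annotated_mh.update({f"b{i}": "low" for i in range(10)})
    out = exposure_enrichment(_assignment(10, 10), none_annotated_mh)
    assert out.flagged

    with pytest.raises(InputError):
        exposure_enrichment(_assignment(2, 2), {"a0": "low"})


def test_microglia_scan_extreme_and_null_overlaps():
    mset = {f"m{i}" for i in range(72)}
    genes = [f"x{i}" for i in range(200)]
    sets = {"identical": set(mset), "disjoint": set(genes[:72])}
    scan = microglia_scan(sets, mset, universe_size=15071)
    assert scan.overlap["identical"] == 72
    assert scan.p["identical"] < 1e-100
    assert scan.enriched["identical"]
    assert scan.p["disjoint"] > 0.2
    assert not scan.enriched["disjoint"]
    assert scan.fraction_enriched == pytest.approx(0.5)

    with pytest.raises(InputError):
        microglia_scan(sets, mset, universe_size=100)
    with pytest.raises(InputError):
        microglia_scan(sets, set(), universe_size=15071)


def test_microglia_p_matches_brute_force_hypergeometric_tail():
    rng = np.random.default_rng(4)
    genes = [f"g{i:03d}" for i in range(100)]
    mset = set(rng.choice(genes, size=12, replace=False))
    sets = {
        f"c{i}": set(rng.choice(genes, size=rng.integers(5, 25), replace=False))
        for i in range(10)
    }
    scan = microglia_scan(sets, mset, universe_size=100)
    for c, cset in sets.items():
        x = len(cset & mset)
        tail = sum(
            comb(12, j) * comb(88, len(cset) - j) / comb(100, len(cset))
            for j in range(x, min(12, len(cset)) + 1)
        )
        assert scan.p[c] == pytest.approx(tail, rel=1e-9)


def test_microglia_cluster_contrast_table():
    mset = {f"m{i}" for i in range(20)}
    sets = {f"b{i}": set(mset) for i in range(3)}
    sets.update({f"a{i}": {f"z{i}{j}" for j in range(5)} for i in range(3)})
    assignment = ClusterAssignment(
        {c: ("B" if c.startswith("b") else "A") for c in sets}, "ward_d", 2
    )
    scan = microglia_scan(sets, mset, universe_size=10_000, assignment=assignment)
    cc = scan.cluster_contrast
    assert cc is not None
    assert (cc.a, cc.b, cc.c, cc.d) == (3, 0, 0, 3)
    assert cc.or_infinite
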