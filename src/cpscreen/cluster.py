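"""Clustering of candidate enrichment profiles and mimicry scans.

Candidates are clustered on their -log10 adjusted-P pathway-enrichment
profiles with Ward hierarchical clustering, labeled so that cluster "A" is
the enrichment-sparse cluster (ties broken toward the larger cluster being
A). Exposure-risk annotations are then compared across clusters as a fold
enrichment of medium/high-risk chemicals plus exact binomial tests, and
each candidate's up-signature is scanned for overlap with the activated-
microglia gene set by Fisher exact test.

Ward linkage note: scipy's ``ward`` method on a condensed distance vector
implements the Ward.D2 recurrence. The default here is the Ward.D variant
(the recurrence applied to unsquared distances, as in R's ``hclust
ward.D``), obtained by feeding the square roots of the Euclidean
distances: that monotone transform reproduces Ward.D's merge order, hence
the identical k-cut partition. ``linkage='ward_d2'`` uses the distances
directly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .cgea import EnrichmentMatrix, bh_adjust
from .matching import BinomialResult, OverlapResult, binomial_test, overlap_odds
from .signatures import InputError

PADJ_FLOOR = 1e-300


@dataclass(frozen=True)
class ClusterAssignment:
    """Chemical -> cluster label, labels ordered by enrichment density.

    Label "A" is the cluster with the lower mean feature value (fewer /
    weaker pathway enrichments); on ties the larger cluster is "A".
    """

    labels: Dict[str, str]
    linkage: str
    k: int

    def members(self, label: str) -> FrozenSet[str]:
        return frozenset(c for c, l in self.labels.items() if l == label)

    @property
    def cluster_names(self) -> List[str]:
        return sorted(set(self.labels.values()))


@dataclass(frozen=True)
class MicrogliaScan:
    overlap: Dict[str, int]
    p: Dict[str, float]
    padj: Dict[str, float]
    enriched: Dict[str, bool]
    fraction_enriched: float
    cluster_contrast: Optional[OverlapResult] = None


@dataclass(frozen=True)
class ExposureEnrichment:
    fold: float
    counts: Dict[str, Dict[str, int]]          # cluster -> {medium_high, total}
    binomial_split: BinomialResult             # med/high split across clusters
    binomial_half: BinomialResult              # same split against p0 = 0.5
    flagged: bool = False                      # a cluster had no annotations


def build_feature_matrix(
    matrix: EnrichmentMatrix,
    candidates: Iterable[str],
    selected_pathways: Iterable[str],
) -> pd.DataFrame:
    """Candidates x selected pathways matrix of -log10 adjusted P.

    Adjusted P is floored at 1e-300 against underflow and capped at 1, so
    non-enriched cells map to 0.
    """
    candidates = sorted(set(candidates))
    pathways = sorted(set(selected_pathways))
    if not pathways:
        raise InputError("empty pathway selection")
    if not candidates:
        raise InputError("empty candidate set")
    sub = matrix.padj.loc[candidates, pathways].to_numpy(dtype=float)
    sub = np.clip(sub, PADJ_FLOOR, 1.0)
    return pd.DataFrame(-np.log10(sub), index=candidates, columns=pathways)


def hierarchical_cluster(
    features: pd.DataFrame,
    k: int = 2,
    linkage: str = "ward_d",
) -> ClusterAssignment:
    """Ward hierarchical clustering of the feature rows, cut into k clusters."""
    n = features.shape[0]
    if k < 1:
        raise InputError("k must be >= 1")
    if k > n:
        raise InputError(f"k={k} exceeds the number of rows ({n})")
    ids = list(features.index)
    if k == 1:
        return ClusterAssignment({c: "A" for c in ids}, linkage, 1)
    if linkage not in ("ward_d", "ward_d2"):
        raise InputError("linkage must be 'ward_d' or 'ward_d2'")

    dist = pdist(features.to_numpy(dtype=float), metric="euclidean")
    if linkage == "ward_d":
        dist = np.sqrt(dist)
    tree = scipy_linkage(dist, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")

    # Order clusters by enrichment density (mean feature value); sparse and,
    # on ties, larger clusters get earlier letters ("A" = sparse cluster).
    values = features.to_numpy(dtype=float)
    stats_per_cluster = []
    for cl in np.unique(raw):
        mask = raw == cl
        stats_per_cluster.append((float(values[mask].mean()), -int(mask.sum()), int(cl)))
    order = [cl for _, _, cl in sorted(stats_per_cluster)]
    letters = {cl: string.ascii_uppercase[i] for i, cl in enumerate(order)}
    labels = {c: letters[raw[i]] for i, c in enumerate(ids)}
    return ClusterAssignment(labels, linkage, k)


def exposure_enrichment(
    assignment: ClusterAssignment,
    annotations: Mapping[str, str],
) -> ExposureEnrichment:
    """Fold enrichment of medium/high exposure risk in cluster B vs A.

    fold = (medium/high fraction in B) / (medium/high fraction in A). Two
    exact binomial constructions of the cluster-B bias are reported: the
    split of all medium/high chemicals across clusters against p0 =
    |B| / (|A| + |B|), and the same split against p0 = 0.5.
    """
    missing = [c for c in assignment.labels if c not in annotations]
    if missing:
        raise InputError(f"unannotated candidates: {sorted(missing)[:5]}...")
    bad = {annotations[c] for c in assignment.labels} - {"high", "medium", "low"}
    if bad:
        raise InputError(f"invalid exposure labels: {sorted(bad)}")

    counts: Dict[str, Dict[str, int]] = {}
    for name in assignment.cluster_names:
        members = assignment.members(name)
        mh = sum(1 for c in members if annotations[c] in ("high", "medium"))
        counts[name] = {"medium_high": mh, "total": len(members)}

    a, b = counts.get("A"), counts.get("B")
    flagged = False
    fold = float("nan")
    if a and b and a["total"] and b["total"]:
        frac_a = a["medium_high"] / a["total"]
        frac_b = b["medium_high"] / b["total"]
        if frac_a > 0:
            fold = frac_b / frac_a
        else:
            flagged = True
    else:
        flagged = True

    k = b["medium_high"] if b else 0
    n = (a["medium_high"] if a else 0) + k
    n_chems = (a["total"] if a else 0) + (b["total"] if b else 0)
    p0 = b["total"] / n_chems if (b and n_chems) else 0.5
    if n > 0 and 0.0 < p0 < 1.0:
        split = binomial_test(k, n, p0)
        half = binomial_test(k, n, 0.5)
    else:
        flagged = True
        split = half = BinomialResult(k=k, n=max(n, 0), p0=p0, p_value=float("nan"))
    return ExposureEnrichment(
        fold=fold, counts=counts, binomial_split=split, binomial_half=half,
        flagged=flagged,
    )


def microglia_scan(
    chem_sets: Mapping[str, Iterable[str]],
    microglia_set: Iterable[str],
    universe_size: int,
    assignment: Optional[ClusterAssignment] = None,
    alpha: float = 0.05,
) -> MicrogliaScan:
    """Fisher overlap of each candidate up-signature with the microglia set.

    One-sided Fisher P over a background of ``universe_size`` genes,
    BH-corrected across candidates; a chemical is called enriched at
    adjusted P < alpha. With a cluster assignment, the enriched flag is
    additionally contrasted across clusters (enriched x cluster-B table).
    """
    mset = frozenset(microglia_set)
    if not mset:
        raise InputError("microglia set is empty")
    ids = sorted(chem_sets)
    if not ids:
        raise InputError("no chemical sets supplied")
    overlaps, pvals = {}, []
    for c in ids:
        cset = frozenset(chem_sets[c])
        union = len(cset | mset)
        if universe_size < union:
            raise InputError(
                f"universe_size={universe_size} smaller than union for {c} ({union})"
            )
        ov = len(cset & mset)
        overlaps[c] = ov
        pvals.append(
            float(stats.hypergeom.sf(ov - 1, universe_size, len(mset), len(cset)))
        )
    padj = bh_adjust(np.clip(pvals, 0.0, 1.0))
    enriched = {c: bool(padj[i] < alpha) for i, c in enumerate(ids)}
    fraction = sum(enriched.values()) / len(ids)

    contrast = None
    if assignment is not None and set(assignment.labels) >= set(ids):
        enriched_set = {c for c in ids if enriched[c]}
        cluster_b = {c for c in ids if assignment.labels[c] == "B"}
        contrast = overlap_odds(enriched_set, cluster_b, len(ids))
    return MicrogliaScan(
        overlap=overlaps,
        p={c: float(pvals[i]) for i, c in enumerate(ids)},
        padj={c: float(padj[i]) for i, c in enumerate(ids)},
        enriched=enriched,
        fraction_enriched=fraction,
        cluster_contrast=contrast,
    )
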