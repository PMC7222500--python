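"""Synthetic study generator with planted ground truth.

Emulates the inputs of the chemical screen: two small microarray-style
contrasts (test group vs. adult reference) sharing a pool of "plasticity
brake" genes downregulated in both, a CTD-style chemical--gene interaction
table in which a planted minority of chemicals up-regulates those brake
genes, a pathway library whose planted sets overlap the disruptors' genes,
an LPS-activated-microglia gene set, and exposure-risk labels biased toward
one planted chemical cluster.

Every artifact draws from its own RNG stream derived from the master seed
by a fixed offset, so regenerating one artifact never shifts another:

======================  ==============
artifact                stream seed
======================  ==============
ground truth            seed + 0
expression (contrast1)  seed + 1
expression (contrast2)  seed + 2
interaction table       seed + 3
pathway library         seed + 4
microglia set           seed + 5
exposure labels         seed + 6
======================  ==============

The planted cluster structure splits the brake pool into two disjoint
subpools: cluster-B disruptors (and the planted "inflammatory-like"
pathways and the microglia set) draw from the larger subpool, cluster-A
disruptors and their pathways from the smaller one, so that candidate
chemicals separate into two enrichment-profile clusters downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from . import io

_STREAM_OFFSETS = {
    "truth": 0,
    "juvenile": 1,
    "lynx1": 2,
    "interactions": 3,
    "pathways": 4,
    "microglia": 5,
    "exposure": 6,
}

CONTRAST_TAGS = ("juvenile", "lynx1")


def _rng(config: SimConfig, artifact: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + _STREAM_OFFSETS[artifact])


def gene_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def chemical_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"C{i:0{width}d}" for i in range(1, n + 1)]


def pathway_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SyntheticTruth:
    """Planted structure of one synthetic study."""

    disruptor_ids: FrozenSet[str]
    planted_pathway_ids: FrozenSet[str]
    cluster_labels: Dict[str, str]           # disruptor id -> "A" / "B"
    brake_genes: FrozenSet[str]
    decoy_genes: FrozenSet[str]
    brake_subpool_b: FrozenSet[str]          # cluster-B brake subpool
    brake_subpool_a: FrozenSet[str]
    pathway_clusters: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "disruptor_ids": sorted(self.disruptor_ids),
            "planted_pathway_ids": sorted(self.planted_pathway_ids),
            "cluster_labels": dict(sorted(self.cluster_labels.items())),
            "brake_genes": sorted(self.brake_genes),
            "decoy_genes": sorted(self.decoy_genes),
            "brake_subpool_b": sorted(self.brake_subpool_b),
            "brake_subpool_a": sorted(self.brake_subpool_a),
            "pathway_clusters": dict(sorted(self.pathway_clusters.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            disruptor_ids=frozenset(d["disruptor_ids"]),
            planted_pathway_ids=frozenset(d["planted_pathway_ids"]),
            cluster_labels=dict(d["cluster_labels"]),
            brake_genes=frozenset(d["brake_genes"]),
            decoy_genes=frozenset(d["decoy_genes"]),
            brake_subpool_b=frozenset(d["brake_subpool_b"]),
            brake_subpool_a=frozenset(d["brake_subpool_a"]),
            pathway_clusters=dict(d.get("pathway_clusters", {})),
        )


def generate_truth(config: SimConfig) -> SyntheticTruth:
    """Draw the planted structure shared by all artifacts."""
    rng = _rng(config, "truth")
    genes = np.array(gene_ids(config.n_genes))
    chems = np.array(chemical_ids(config.n_chemicals))
    paths = np.array(pathway_ids(config.n_pathways))

    planted_gene_idx = rng.choice(
        config.n_genes, size=2 * config.n_brake_genes, replace=False
    )
    brake = genes[planted_gene_idx[: config.n_brake_genes]]
    decoy = genes[planted_gene_idx[config.n_brake_genes:]]

    # Equal-sized disjoint brake subpools: each cluster's disruptors and
    # pathways draw from their own subpool at the same density, so cluster
    # B's higher enrichment density comes from its larger pathway count.
    n_b_pool = config.n_brake_genes // 2
    pool_b = brake[:n_b_pool]
    pool_a = brake[n_b_pool:]

    disruptors = np.sort(
        chems[rng.choice(config.n_chemicals, size=config.n_planted_disruptors,
                         replace=False)]
    )
    n_b = int(round(config.cluster_b_frac * config.n_planted_disruptors))
    b_members = set(
        disruptors[rng.choice(len(disruptors), size=n_b, replace=False)]
    )
    labels = {c: ("B" if c in b_members else "A") for c in disruptors}

    planted_paths = np.sort(
        paths[rng.choice(config.n_pathways, size=config.n_planted_pathways,
                         replace=False)]
    )
    n_pb = int(round(config.cluster_b_frac * config.n_planted_pathways))
    pb_members = set(
        planted_paths[rng.choice(len(planted_paths), size=n_pb, replace=False)]
    )
    pathway_clusters = {p: ("B" if p in pb_members else "A") for p in planted_paths}

    return SyntheticTruth(
        disruptor_ids=frozenset(disruptors),
        planted_pathway_ids=frozenset(planted_paths),
        cluster_labels=labels,
        brake_genes=frozenset(brake),
        decoy_genes=frozenset(decoy),
        brake_subpool_b=frozenset(pool_b),
        brake_subpool_a=frozenset(pool_a),
        pathway_clusters=pathway_clusters,
    )


def generate_expression(
    config: SimConfig, contrast_tag: str, truth: SyntheticTruth | None = None
) -> Tuple[pd.DataFrame, pd.Series]:
    """One contrast: genes x (test + adult reference) log2 intensities.

    Brake genes are shifted by -effect_size in the test group, an
    equal-sized decoy set by +effect_size; everything else is null.
    Returns the matrix and a sample -> group label Series.
    """
    if contrast_tag not in CONTRAST_TAGS:
        raise ConfigError(f"unknown contrast tag {contrast_tag!r}; use one of {CONTRAST_TAGS}")
    if truth is None:
        truth = generate_truth(config)
    rng = _rng(config, contrast_tag)

    genes = gene_ids(config.n_genes)
    n = config.n_samples_per_group
    samples = [f"{contrast_tag}_{i + 1}" for i in range(n)] + [
        f"adult_{contrast_tag}_{i + 1}" for i in range(n)
    ]
    groups = pd.Series(
        [contrast_tag] * n + ["adult"] * n, index=samples, name="group"
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.tile(baseline[:, None], (1, 2 * n))

    gene_index = {g: i for i, g in enumerate(genes)}
    brake_idx = np.array(sorted(gene_index[g] for g in truth.brake_genes))
    decoy_idx = np.array(sorted(gene_index[g] for g in truth.decoy_genes))
    values[brake_idx, :n] -= config.effect_size
    values[decoy_idx, :n] += config.effect_size
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples), groups


def generate_chemical_interactions(
    config: SimConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """CTD-style interaction table, including records the parser must drop.

    Planted disruptors draw ``disruptor_overlap_frac`` of their
    "increases expression" genes from their cluster's brake subpool;
    everything else is uniform over the universe. Distractor records with a
    non-mRNA target type and records with an empty reference field are
    appended to exercise the parsing filters.
    """
    rng = _rng(config, "interactions")
    genes = np.array(gene_ids(config.n_genes))
    chems = chemical_ids(config.n_chemicals)
    lo, hi = config.chem_set_size_range
    gene_arr = genes

    rows: List[tuple] = []

    def _pm() -> str:
        refs = rng.integers(10_000_000, 35_000_000, size=rng.integers(1, 4))
        return "|".join(str(r) for r in refs)

    # Planted disruptors draw set sizes from the upper half of the range:
    # a set of a handful of genes cannot carry a planted cluster signature,
    # so the planted chemicals are the ones with informative set sizes.
    planted_lo = (lo + hi) // 2

    for chem in chems:
        name = f"chemical {chem.lower()}"
        size_lo = planted_lo if chem in truth.disruptor_ids else lo
        n_up = int(rng.integers(size_lo, hi + 1))
        n_down = int(rng.integers(lo, hi + 1))

        if chem in truth.disruptor_ids:
            pool = (
                truth.brake_subpool_b
                if truth.cluster_labels[chem] == "B"
                else truth.brake_subpool_a
            )
            pool = np.array(sorted(pool))
            n_brake = min(int(round(config.disruptor_overlap_frac * n_up)), len(pool))
            brake_part = rng.choice(pool, size=n_brake, replace=False)
            rest_pool = np.setdiff1d(gene_arr, brake_part, assume_unique=False)
            rest = rng.choice(rest_pool, size=n_up - n_brake, replace=False)
            up_genes = np.concatenate([brake_part, rest])
        else:
            up_genes = rng.choice(gene_arr, size=n_up, replace=False)
        down_pool = np.setdiff1d(gene_arr, up_genes)
        down_genes = rng.choice(down_pool, size=min(n_down, len(down_pool)), replace=False)

        for g in up_genes:
            rows.append((chem, name, g, "Mus musculus",
                         "increases^expression", "mRNA", _pm()))
        for g in down_genes:
            rows.append((chem, name, g, "Mus musculus",
                         "decreases^expression", "mRNA", _pm()))

    # Distractors: non-mRNA target types and reference-less records. These
    # must be filtered out downstream and never count toward set sizes.
    n_valid = len(rows)
    n_distract = max(1, int(np.ceil(config.distractor_frac * n_valid)))
    n_noref = max(1, int(np.ceil(config.noref_frac * n_valid)))
    distract_types = np.array(["protein", "activity"])
    for _ in range(n_distract):
        chem = chems[int(rng.integers(config.n_chemicals))]
        g = str(rng.choice(gene_arr))
        action = "increases^expression" if rng.random() < 0.5 else "decreases^expression"
        rows.append((chem, f"chemical {chem.lower()}", g, "Mus musculus",
                     action, str(rng.choice(distract_types)), _pm()))
    for _ in range(n_noref):
        chem = chems[int(rng.integers(config.n_chemicals))]
        g = str(rng.choice(gene_arr))
        action = "increases^expression" if rng.random() < 0.5 else "decreases^expression"
        rows.append((chem, f"chemical {chem.lower()}", g, "Mus musculus",
                     action, "mRNA", ""))

    return pd.DataFrame(rows, columns=io.INTERACTION_COLUMNS)


def generate_pathways_and_annotations(
    config: SimConfig, truth: SyntheticTruth
) -> Tuple[Dict[str, List[str]], List[str], Dict[str, str]]:
    """Pathway GMT sets, the microglia gene set, and exposure labels.

    Planted pathways draw ``planted_pathway_overlap_frac`` of their members
    from their cluster's brake subpool (a subset of the disruptors'
    up-gene union); the microglia set draws mostly from the cluster-B
    subpool; exposure labels are medium/high with probability
    ``exposure_bias`` for cluster-B disruptors and with the background rate
    otherwise.
    """
    rng = _rng(config, "pathways")
    genes = np.array(gene_ids(config.n_genes))
    paths = pathway_ids(config.n_pathways)
    pool = {
        "B": np.array(sorted(truth.brake_subpool_b)),
        "A": np.array(sorted(truth.brake_subpool_a)),
    }

    sets: Dict[str, List[str]] = {}
    lo, hi = config.pathway_size_range
    plo, phi = config.planted_pathway_size_range
    for p in paths:
        if p in truth.planted_pathway_ids:
            size = int(rng.integers(plo, phi + 1))
            sub = pool[truth.pathway_clusters[p]]
            n_core = min(int(round(config.planted_pathway_overlap_frac * size)), len(sub))
            core = rng.choice(sub, size=n_core, replace=False)
            rest_pool = np.setdiff1d(genes, core)
            rest = rng.choice(rest_pool, size=size - n_core, replace=False)
            members = np.concatenate([core, rest])
        else:
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(genes, size=size, replace=False)
        sets[p] = sorted(members)

    mrng = _rng(config, "microglia")
    n_core = min(
        int(round(config.microglia_planted_frac * config.microglia_set_size)),
        len(pool["B"]),
    )
    core = mrng.choice(pool["B"], size=n_core, replace=False)
    rest_pool = np.setdiff1d(genes, np.concatenate([core, np.array(sorted(truth.brake_genes))]))
    rest = mrng.choice(rest_pool, size=config.microglia_set_size - n_core, replace=False)
    microglia = sorted(np.concatenate([core, rest]))

    erng = _rng(config, "exposure")
    exposure: Dict[str, str] = {}
    for chem in chemical_ids(config.n_chemicals):
        in_b = truth.cluster_labels.get(chem) == "B"
        p_mh = config.exposure_bias if in_b else config.background_exposure_rate
        if erng.random() < p_mh:
            exposure[chem] = "high" if erng.random() < 0.5 else "medium"
        else:
            exposure[chem] = "low"
    return sets, microglia, exposure


def simulate_study(config: SimConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate and write every pipeline input under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)

    for tag in CONTRAST_TAGS:
        matrix, groups = generate_expression(config, tag, truth)
        io.write_matrix(matrix, out / f"expression_{tag}.tsv")
        io.write_labels(groups, out / f"labels_{tag}.tsv")

    interactions = generate_chemical_interactions(config, truth)
    io.write_interactions(interactions, out / "interactions.tsv")

    sets, microglia, exposure = generate_pathways_and_annotations(config, truth)
    io.write_gmt(sets, out / "pathways.gmt")
    io.write_gmt({"microglia_lps_up": microglia}, out / "microglia.gmt")
    io.write_exposure(exposure, out / "exposure.tsv")

    # Identity ortholog-mapping table so the universe filter is exercised.
    ids = gene_ids(config.n_genes)
    io.write_mapping(
        pd.DataFrame({"source_id": ids, "target_id": ids}), out / "gene_mapping.tsv"
    )

    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))
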