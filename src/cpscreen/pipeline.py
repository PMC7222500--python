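"""End-to-end orchestration: simulate -> signatures -> libraries -> GSEA ->
candidates -> CGEA -> clustering -> microglia scan, with one master seed.

Each stochastic stage derives its own seed from the master seed by a fixed
offset (simulation uses the master seed directly; GSEA runs use
``seed + 100 + index`` in a fixed stage order), every intermediate result
is written as plain text under the run directory, and the run report
collects the stage statistics. Reports are deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import cgea as cgea_mod
from . import cluster as cluster_mod
from . import gsea as gsea_mod
from . import io
from . import matching as matching_mod
from . import synthetic
from .chem import build_libraries, parse_interactions
from .config import RunConfig
from .signatures import compute_signature, filter_to_universe, quantile_normalize

logger = logging.getLogger(__name__)

# Fixed order of GSEA stages; each gets seed + 100 + index.
_GSEA_STAGES = (
    ("composite", "juvenile"),
    ("composite", "lynx1"),
    ("up", "juvenile"),
    ("up", "lynx1"),
    ("down", "juvenile"),
    ("down", "lynx1"),
)


class StageError(RuntimeError):
    """A pipeline stage failed; completed outputs are left on disk."""


def _gsea_seed(master_seed: int, library: str, contrast: str) -> int:
    return master_seed + 100 + _GSEA_STAGES.index((library, contrast))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen and return the run report (also written).

    Raises :class:`StageError` naming the failing stage; outputs of
    completed stages persist under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    report: dict = {
        "config": config.to_dict(),
        "seeds": {"master": config.seed},
        "stages": {},
    }
    stage = "setup"
    try:
        for sub in ("inputs", "signatures", "libraries", "gsea", "cgea", "clusters"):
            (out / sub).mkdir(parents=True, exist_ok=True)

        stage = "simulate"
        input_dir = out / "inputs"
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            synthetic.simulate_study(sim, input_dir)
            report["seeds"]["simulation"] = config.seed

        stage = "signatures"
        mapping = io.read_mapping(input_dir / "gene_mapping.tsv")
        signatures = {}
        for tag in synthetic.CONTRAST_TAGS:
            matrix = io.read_matrix(input_dir / f"expression_{tag}.tsv")
            labels = io.read_labels(input_dir / f"labels_{tag}.tsv")
            matrix = quantile_normalize(matrix)
            matrix = filter_to_universe(matrix, mapping)
            sig = compute_signature(
                matrix, labels, test_group=tag, reference_group="adult",
                contrast_name=tag, statistic=config.ranking_statistic,
            )
            signatures[tag] = sig
            io.write_rnk(sig.entries, out / "signatures" / f"{tag}.rnk")
        universe = signatures["juvenile"].universe
        report["stages"]["signatures"] = {
            "universe_size": signatures["juvenile"].universe_size
        }

        stage = "libraries"
        interactions = io.read_interactions(input_dir / "interactions.tsv")
        records = parse_interactions(interactions)
        libraries = build_libraries(records, universe, min_size=config.min_set_size)
        lib_report = {}
        for dialect, lib in libraries.items():
            io.write_gmt(
                {c: sorted(s) for c, s in lib.sets.items()},
                out / "libraries" / f"chem_{dialect}.gmt",
                descriptions=lib.names,
            )
            lo, hi = lib.size_range()
            lib_report[dialect] = {
                "n_chemicals": len(lib), "min_set_size": lo, "max_set_size": hi,
            }
        report["stages"]["libraries"] = {
            "n_raw_records": int(len(interactions)),
            "n_parsed_records": len(records),
            **lib_report,
        }

        stage = "gsea"
        gsea_results: Dict[tuple, list] = {}
        gsea_report = {}
        for dialect, tag in _GSEA_STAGES:
            seed = _gsea_seed(config.seed, dialect, tag)
            results = gsea_mod.score_library(
                signatures[tag], libraries[dialect],
                n_perm=config.n_perm, seed=seed,
                weight_exponent=config.weight_exponent,
            )
            gsea_results[(dialect, tag)] = results
            pd.DataFrame(gsea_mod.results_to_rows(results)).to_csv(
                out / "gsea" / f"{dialect}_{tag}.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            sig_set = gsea_mod.select_significant(
                results, config.p_threshold, config.fdr_threshold
            )
            gsea_report[f"{dialect}_{tag}"] = {
                "n_scored": len(results),
                "n_significant": len(sig_set),
                "seed": seed,
            }
            report["seeds"][f"gsea_{dialect}_{tag}"] = seed
        report["stages"]["gsea"] = gsea_report

        stage = "matching"
        direction = {}
        for tag in synthetic.CONTRAST_TAGS:
            sig_ids = gsea_mod.select_significant(
                gsea_results[("composite", tag)],
                config.p_threshold, config.fdr_threshold,
            )
            sig_results = [
                r for r in gsea_results[("composite", tag)]
                if r.chemical_id in sig_ids
            ]
            if sig_results:
                bias = matching_mod.direction_bias_test(sig_results)
                direction[tag] = {
                    "k_negative": bias.k, "n": bias.n, "p_value": bias.p_value,
                }
            else:
                direction[tag] = {"k_negative": 0, "n": 0, "p_value": None}

        updown = {}
        neg_up: Dict[str, frozenset] = {}
        for tag in synthetic.CONTRAST_TAGS:
            up_sig = gsea_mod.select_significant(
                gsea_results[("up", tag)], config.p_threshold,
                config.fdr_threshold, "negative",
            )
            down_sig = gsea_mod.select_significant(
                gsea_results[("down", tag)], config.p_threshold,
                config.fdr_threshold, "negative",
            )
            neg_up[tag] = up_sig
            if up_sig or down_sig:
                test = matching_mod.updown_bias_test(
                    up_sig, down_sig, len(libraries["up"]), len(libraries["down"]),
                    null=config.updown_null,
                )
                updown[tag] = {
                    "k_up": test.k, "n": test.n, "p0": test.p0,
                    "p_value": test.p_value,
                }
            else:
                updown[tag] = {"k_up": 0, "n": 0, "p0": None, "p_value": None}

        candidates = matching_mod.intersect_candidates(
            neg_up["juvenile"], neg_up["lynx1"]
        )
        overlap = None
        if neg_up["juvenile"] or neg_up["lynx1"]:
            ov = matching_mod.overlap_odds(
                neg_up["juvenile"], neg_up["lynx1"], len(libraries["up"])
            )
            overlap = {
                "table": [ov.a, ov.b, ov.c, ov.d],
                "odds_ratio": None if ov.or_infinite else ov.odds_ratio,
                "or_infinite": ov.or_infinite,
                "p_value": ov.p_value,
            }
        pd.Series(sorted(candidates), name="chemical_id").to_csv(
            out / "candidates.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report["stages"]["matching"] = {
            "direction_bias": direction,
            "updown_bias": updown,
            "n_candidates": len(candidates),
            "n_significant_up_juvenile": len(neg_up["juvenile"]),
            "n_significant_up_lynx1": len(neg_up["lynx1"]),
            "overlap": overlap,
        }

        stage = "cgea"
        pathways = io.read_gmt(input_dir / "pathways.gmt")
        matrix = cgea_mod.pairwise_enrichment(
            libraries["up"], pathways, universe,
            alpha=config.alpha, bh_scope=config.bh_scope,
        )
        matrix.padj.to_csv(out / "cgea" / "padj.tsv", sep="\t",
                           index_label="chemical_id", lineterminator="\n")
        matrix.binary.to_csv(out / "cgea" / "binary.tsv", sep="\t",
                             index_label="chemical_id", lineterminator="\n")
        scored_candidates = candidates & set(matrix.chemicals)
        over = cgea_mod.pathway_overrepresentation(matrix, scored_candidates)
        pd.DataFrame([dataclasses.asdict(r) for r in over]).to_csv(
            out / "cgea" / "overrepresentation.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        selected = cgea_mod.select_pathways(over, config.alpha)
        report["stages"]["cgea"] = {
            "n_tests": matrix.n_tests,
            "n_chemicals": len(matrix.chemicals),
            "n_pathways": len(matrix.pathways),
            "n_binary_calls": int(matrix.binary.to_numpy().sum()),
            "n_selected_pathways": len(selected),
        }

        stage = "cluster"
        cluster_report: dict = {"skipped": None}
        assignment: Optional[cluster_mod.ClusterAssignment] = None
        if len(scored_candidates) >= config.n_clusters and selected:
            features = cluster_mod.build_feature_matrix(
                matrix, scored_candidates, selected
            )
            features.to_csv(out / "clusters" / "features.tsv", sep="\t",
                            index_label="chemical_id", lineterminator="\n")
            assignment = cluster_mod.hierarchical_cluster(
                features, k=config.n_clusters, linkage=config.linkage
            )
            pd.Series(assignment.labels, name="cluster").rename_axis(
                "chemical_id"
            ).sort_index().to_csv(out / "clusters" / "assignment.tsv", sep="\t",
                                  lineterminator="\n")
            sizes = {
                name: len(assignment.members(name))
                for name in assignment.cluster_names
            }
            exposure = io.read_exposure(input_dir / "exposure.tsv")
            exp = cluster_mod.exposure_enrichment(assignment, exposure)
            cluster_report = {
                "skipped": None,
                "cluster_sizes": sizes,
                "exposure_fold": exp.fold,
                "exposure_counts": exp.counts,
                "exposure_binomial_split_p": exp.binomial_split.p_value,
                "exposure_binomial_half_p": exp.binomial_half.p_value,
                "exposure_flagged": exp.flagged,
            }
        else:
            cluster_report["skipped"] = (
                "not enough candidates or no selected pathways"
            )
        report["stages"]["cluster"] = cluster_report

        stage = "microglia"
        microglia_sets = io.read_gmt(input_dir / "microglia.gmt")
        mset = set(next(iter(microglia_sets.values()))) & universe
        universe_size = config.microglia_universe_size or len(universe)
        micro_report: dict = {"skipped": None}
        if scored_candidates:
            cand_sets = {
                c: libraries["up"].sets[c]
                for c in sorted(scored_candidates)
                if c in libraries["up"].sets
            }
            scan = cluster_mod.microglia_scan(
                cand_sets, mset, universe_size, assignment=assignment,
                alpha=config.alpha,
            )
            pd.DataFrame(
                {
                    "chemical_id": sorted(cand_sets),
                    "overlap": [scan.overlap[c] for c in sorted(cand_sets)],
                    "p": [scan.p[c] for c in sorted(cand_sets)],
                    "padj": [scan.padj[c] for c in sorted(cand_sets)],
                    "enriched": [int(scan.enriched[c]) for c in sorted(cand_sets)],
                }
            ).to_csv(out / "clusters" / "microglia.tsv", sep="\t", index=False,
                     lineterminator="\n")
            micro_report = {
                "skipped": None,
                "fraction_enriched": scan.fraction_enriched,
                "n_enriched": sum(scan.enriched.values()),
                "universe_size": universe_size,
            }
            if scan.cluster_contrast is not None:
                cc = scan.cluster_contrast
                micro_report["cluster_contrast"] = {
                    "table": [cc.a, cc.b, cc.c, cc.d],
                    "odds_ratio": None if cc.or_infinite else cc.odds_ratio,
                    "or_infinite": cc.or_infinite,
                    "p_value": cc.p_value,
                }
        else:
            micro_report["skipped"] = "no candidates"
        report["stages"]["microglia"] = micro_report

    except Exception as exc:
        raise StageError(f"pipeline stage '{stage}' failed: {exc}") from exc

    io.write_json(report, out / "report.json")
    return report


def evaluate_against_truth(report_dir: str | Path, report: dict) -> dict:
    """Recovery metrics of one synthetic run against its planted truth.

    Returns candidate sensitivity and false-discovery rate, planted-pathway
    recovery and non-planted selection rate, and the adjusted Rand index of
    the cluster assignment against the planted labels.
    """
    from sklearn.metrics import adjusted_rand_score

    out = Path(report_dir)
    truth = synthetic.load_truth(out / "inputs" / "truth.json")

    cand_df = pd.read_csv(out / "candidates.tsv", sep="\t")
    candidates = set(cand_df["chemical_id"]) if len(cand_df) else set()
    planted = set(truth.disruptor_ids)
    tp = len(candidates & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = (len(candidates) - tp) / len(candidates) if candidates else 0.0

    over = pd.read_csv(out / "cgea" / "overrepresentation.tsv", sep="\t")
    selected = set(over.loc[over["padj"] < report["config"]["alpha"], "pathway_id"])
    planted_paths = set(truth.planted_pathway_ids)
    n_nonplanted = len(over) - len(planted_paths & set(over["pathway_id"]))
    pathway_recovery = (
        len(selected & planted_paths) / len(planted_paths)
        if planted_paths else float("nan")
    )
    nonplanted_rate = (
        len(selected - planted_paths) / n_nonplanted if n_nonplanted else 0.0
    )

    ari = float("nan")
    assignment_path = out / "clusters" / "assignment.tsv"
    if assignment_path.exists():
        assign = pd.read_csv(assignment_path, sep="\t").set_index("chemical_id")[
            "cluster"
        ]
        common = sorted(set(assign.index) & set(truth.cluster_labels))
        if len(common) >= 2:
            ari = float(
                adjusted_rand_score(
                    [truth.cluster_labels[c] for c in common],
                    [assign[c] for c in common],
                )
            )

    return {
        "candidate_sensitivity": sensitivity,
        "candidate_fdr": fdr,
        "n_candidates": len(candidates),
        "pathway_recovery": pathway_recovery,
        "nonplanted_selection_rate": nonplanted_rate,
        "clustering_ari": ari,
    }
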