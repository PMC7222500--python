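"""Shared fixtures: toy rankings and a scaled-down synthetic study."""

from __future__ import annotations

import pytest

from cpscreen import RunConfig, SimConfig, RankedSignature, run_pipeline


@pytest.fixture
def toy_signature() -> RankedSignature:
    """Four-gene ranking used by the hand-stepped enrichment examples."""
    return RankedSignature(
        contrast_name="toy",
        entries=(("a", 3.0), ("b", 2.0), ("c", 1.0), ("d", 0.5)),
    )


@pytest.fixture
def small_config() -> SimConfig:
    """Down-scaled study for fast unit tests."""
    return SimConfig(
        n_genes=400,
        n_brake_genes=60,
        n_chemicals=60,
        n_planted_disruptors=10,
        chem_set_size_range=(5, 30),
        n_pathways=60,
        n_planted_pathways=6,
        pathway_size_range=(5, 20),
        planted_pathway_size_range=(15, 25),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One fast end-to-end pipeline run on a small synthetic study."""
    out = tmp_path_factory.mktemp("small_run")
    config = RunConfig(
        out_dir=out,
        seed=11,
        n_perm=200,
        sim=SimConfig(
            n_genes=400,
            n_brake_genes=60,
            n_chemicals=60,
            n_planted_disruptors=10,
            chem_set_size_range=(5, 30),
            n_pathways=60,
            n_planted_pathways=6,
            pathway_size_range=(5, 20),
            planted_pathway_size_range=(15, 25),
        ),
    )
    report = run_pipeline(config)
    return config, report
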