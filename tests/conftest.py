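"""Shared fixtures: one synthetic pathway universe and reference cohorts.

The demo scale used throughout the suite is 25 pathways x 10 genes x 2
SNPs per gene (500 SNPs after mapping) with 300 cases / 300 controls --
small enough for full pipeline runs in seconds, large enough that the
pathway-level statistics behave as designed.
"""

import numpy as np
import pytest

import pathepi as pe

UNIVERSE_SEED = 1
STRONG_EFFECT = dict(
    kind="BPM", pathway_a="PW0001", pathway_b="PW0002", coding="dominant",
    direction="risk", effect_log_odds=float(np.log(3.0)), pair_fraction=0.3,
)


@pytest.fixture(scope="session")
def universe():
    genes, pathways = pe.generate_pathway_universe(
        n_genes=260, n_pathways=25, genes_per_pathway_range=(10, 10),
        seed=UNIVERSE_SEED,
    )
    return genes, pathways


def make_cohort(universe, truth=(), seed=0, n_cases=300, n_controls=300, **kw):
    genes, pathways = universe
    return pe.generate_cohort(
        genes, pathways, n_cases, n_controls, truth=truth, seed=seed, **kw
    )


def make_spm(universe, dataset):
    genes, pathways = universe
    snp_gene = pe.map_snps_to_genes(dataset.snps, genes, 50_000)
    return pe.build_snp_pathway_matrix(snp_gene, pathways,
                                       snp_ids=dataset.snp_ids)


@pytest.fixture(scope="session")
def planted_cohort(universe):
    ds, truth = make_cohort(universe, truth=[pe.EffectConfig(**STRONG_EFFECT)],
                            seed=5)
    return ds, truth


@pytest.fixture(scope="session")
def planted_spm(universe, planted_cohort):
    return make_spm(universe, planted_cohort[0])


@pytest.fixture(scope="session")
def null_cohort(universe):
    ds, _ = make_cohort(universe, truth=(), seed=11)
    return ds


@pytest.fixture(scope="session")
def null_spm(universe, null_cohort):
    return make_spm(universe, null_cohort)


@pytest.fixture(scope="session")
def null_network(null_cohort):
    return pe.build_interaction_network(null_cohort, "dominant", 0.05)
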