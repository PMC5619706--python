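"""Simulate the study cohorts: three case-control cohorts sharing one
planted between-pathway interaction, plus one pure-null cohort.

Writes PED/MAP genotypes, gene table, GMT pathways and the planted truth
under results/data/<cohort>/.
"""

import os

import numpy as np

import pathepi as pe

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")
SEED = 20260924

PLANTED = pe.EffectConfig(
    kind="BPM", pathway_a="PW0001", pathway_b="PW0002", coding="dominant",
    direction="risk", effect_log_odds=float(np.log(3.0)), pair_fraction=0.3,
)


def main() -> None:
    genes, pathways = pe.generate_pathway_universe(
        n_genes=260, n_pathways=25, genes_per_pathway_range=(10, 10),
        seed=SEED,
    )
    print(f"universe: {len(genes)} genes, {len(pathways)} pathways")
    for k in range(3):
        ds, truth = pe.generate_cohort(
            genes, pathways, 300, 300, truth=[PLANTED], seed=SEED + 1 + k,
            missing_rate=0.01,
            ld_block_config=pe.LDBlockConfig(n_blocks=10, block_size=2,
                                             flip_prob=0.02),
        )
        out = os.path.join(OUT, f"cohort{k + 1}")
        pe.export_dataset(ds, genes, pathways, out, truth=truth)
        print(f"cohort{k + 1}: {ds.n_samples} samples x {ds.n_snps} SNPs, "
              f"{len(truth.effects[0].causal_pairs)} planted causal pairs "
              f"-> {out}")
    ds0, _ = pe.generate_cohort(genes, pathways, 300, 300, seed=SEED + 9,
                                missing_rate=0.01)
    out = os.path.join(OUT, "null")
    pe.export_dataset(ds0, genes, pathways, out)
    print(f"null cohort: {ds0.n_samples} samples x {ds0.n_snps} SNPs -> {out}")


if __name__ == "__main__":
    main()
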