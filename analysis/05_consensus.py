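"""Consensus analysis across the three cohorts.

Keeps blocks with all statistics nominally significant in >= 2 cohorts,
ranks them by the geometric mean of supporting permutation p-values, and
derives an empirical significance for the consensus counts from the
per-cohort sample-permutation runs.
"""

import os

import pathepi as pe

HERE = os.path.dirname(__file__)
OUT = os.path.join(HERE, "..", "results", "consensus")
CUTOFFS = (5e-4, 1e-3, 5e-3, 1e-2, 5e-2)


def main() -> None:
    results = {}
    perm_runs = {}
    for k in (1, 2, 3):
        ds, genes, pathways = pe.import_dataset(
            os.path.join(HERE, "..", "results", "data", f"cohort{k}"))
        clean, _ = pe.preprocess(ds, pe.QCConfig(ld_r2_threshold=0.3, max_ibd=0.45), seed=0)
        snp_gene = pe.map_snps_to_genes(clean.snps, genes, 50_000)
        spm = pe.build_snp_pathway_matrix(snp_gene, pathways,
                                          snp_ids=clean.snp_ids)
        res = pe.run_interaction_discovery(clean, spm, "dominant", 0.05,
                                           n_perm=2000, n_sample_perm=10,
                                           seed=10 + k)
        results[f"cohort{k}"] = res.results
        perm_runs[f"cohort{k}"] = res.permutation_runs
        print(f"cohort{k}: {len(res.significant(0.25))} discoveries at "
              f"FDR <= 0.25")

    cons = pe.consensus_interactions(results)
    print(f"{len(cons)} consensus records supported by >= 2 cohorts; top:")
    print(cons.head(5).to_string(index=False))
    real_counts = {c: int((cons["geomean_p"] <= c).sum()) for c in CUTOFFS}
    null = pe.consensus_null(perm_runs, real_counts, cutoffs=CUTOFFS,
                             n_resample=100, seed=99)
    print(null.to_string(index=False))
    os.makedirs(OUT, exist_ok=True)
    cons.to_csv(os.path.join(OUT, "consensus.tsv"), sep="\t", index=False)
    null.to_csv(os.path.join(OUT, "consensus_null.tsv"), sep="\t",
                index=False)
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
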