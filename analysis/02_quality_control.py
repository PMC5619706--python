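"""Quality control of cohort 1: missingness, MAF, Hardy-Weinberg,
relatedness, LD pruning and case-control balancing.

Reads results/data/cohort1, writes the QC report to results/qc/.
"""

import os

import pathepi as pe

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data",
                    "cohort1")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "qc")


def main() -> None:
    ds, genes, pathways = pe.import_dataset(DATA)
    print(f"input: {ds.n_samples} samples x {ds.n_snps} SNPs "
          f"({ds.n_cases} cases / {ds.n_controls} controls)")
    clean, report = pe.preprocess(ds, pe.QCConfig(ld_r2_threshold=0.3, max_ibd=0.45),
                                  seed=0)
    for step in report.steps:
        print(f"  {step['reason']:<16} removed {len(step['removed']):>4} "
              f"({step['n_before']} -> {step['n_after']})")
    print(f"output: {clean.n_samples} samples x {clean.n_snps} SNPs")
    os.makedirs(OUT, exist_ok=True)
    report.to_frame().to_csv(os.path.join(OUT, "qc_report.tsv"), sep="\t",
                             index=False)
    print(f"report -> {os.path.join(OUT, 'qc_report.tsv')}")


if __name__ == "__main__":
    main()
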