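"""End-to-end orchestration: QC -> mapping -> network -> tests -> FDR.

The in-memory engine :func:`run_interaction_discovery` computes the real
block-test table plus ``n_sample_perm`` full reruns under case-control
label permutations and attaches the sample-permutation FDR.  The
file-driven :func:`run_discovery` wraps it with dataset import, QC,
mapping, optional pilot model selection, redundancy filtering, TSV
outputs and a JSON manifest of all effective parameters and seeds, so a
run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, GeneRecord, PathwayCollection
from . import io as pio
from .qc import QCConfig, QCReport, ld_prune, match_case_control, qc_filter, \
    remove_related
from .mapping import MappingConfig, SNPPathwayMatrix, build_snp_pathway_matrix, \
    map_snps_to_genes
from .network import InteractionNetwork, build_interaction_network, score_pairs
from .block_tests import KINDS, run_block_tests
from .fdr import pilot_select_model, redundancy_filter, sample_permutation_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "DiscoveryResult",
    "preprocess",
    "permute_phenotype",
    "run_interaction_discovery",
    "run_discovery",
]


@dataclass
class RunConfig:
    """Declarative configuration of one discovery run."""

    data_dir: str = ""
    out_dir: str = "results/discovery"
    qc: QCConfig = field(default_factory=QCConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    model: str = "pilot"  # disease model, or "pilot" to select one
    delta: float = 0.05
    pilot_models: Tuple[str, ...] = ("combined", "dominant", "recessive", "additive")
    pilot_densities: Tuple[float, ...] = (0.02, 0.04, 0.06)
    pilot_n_perm: int = 2000
    n_perm: int = 2000
    n_sample_perm: int = 10
    fdr_report_threshold: float = 0.25
    redundancy_overlap: float = 0.25
    skip_qc: bool = False
    seed: int = 0

    def to_manifest(self) -> Dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["mapping"] = asdict(self.mapping)
        return d


@dataclass
class DiscoveryResult:
    """Bundle of everything a discovery run produced."""

    results: pd.DataFrame  # real block tests with fdr column
    permutation_runs: List[pd.DataFrame]
    network: InteractionNetwork
    spm: SNPPathwayMatrix
    model: str
    delta: float
    nonredundant: Optional[pd.DataFrame] = None
    qc_report: Optional[QCReport] = None
    pilot_table: Optional[pd.DataFrame] = None

    def significant(self, fdr_threshold: float = 0.25) -> pd.DataFrame:
        return self.results[self.results["fdr"] <= fdr_threshold]


def permute_phenotype(dataset: GenotypeDataset, rng: np.random.Generator
                      ) -> GenotypeDataset:
    """Case-control label permutation preserving class counts."""
    return GenotypeDataset(
        dataset.snps, dataset.sample_ids, dataset.dosage,
        rng.permutation(dataset.phenotype),
    )


def preprocess(
    dataset: GenotypeDataset,
    qc_config: QCConfig = QCConfig(),
    seed: int = 0,
    relatedness: bool = True,
) -> Tuple[GenotypeDataset, QCReport]:
    """QC filters, relatedness removal, LD pruning, case-control matching.

    Ancestry-outlier removal against an external reference panel is not
    performed; the covariate-free matching step simply balances class
    sizes (logged as the simplification it is).
    """
    ds, report = qc_filter(dataset, qc_config)
    if relatedness:
        ds, removed = remove_related(ds, qc_config.max_ibd)
        report.add("SAMPLE_RELATED", removed,
                   len(removed) + ds.n_samples)
    logger.info("ancestry outlier removal skipped (no external reference panel)")
    keep = ld_prune(ds, qc_config)
    removed_snps = [s for i, s in enumerate(ds.snp_ids)
                    if i not in set(keep.tolist())]
    report.add("SNP_LD_PRUNED", removed_snps, ds.n_snps)
    ds = ds.subset(snp_idx=keep)
    before = ds.n_samples
    ds = match_case_control(ds, seed=seed)
    report.add("SAMPLE_UNMATCHED",
               [f"({before - ds.n_samples} downsampled)"] if before > ds.n_samples
               else [], before)
    return ds, report


def run_interaction_discovery(
    dataset: GenotypeDataset,
    spm: SNPPathwayMatrix,
    model: str,
    delta: float,
    n_perm: int = 2000,
    n_sample_perm: int = 10,
    seed: int = 0,
    kinds: Sequence[str] = KINDS,
    bpm_pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> DiscoveryResult:
    """Block tests on the real labels and on sample permutations, with FDR."""
    if spm.snp_ids != dataset.snp_ids:
        raise ValueError("membership matrix SNP universe differs from dataset")
    root = np.random.SeedSequence(seed)
    perm_label_seed, sample_perm_seed = root.spawn(2)
    net = build_interaction_network(dataset, model, delta)
    results = run_block_tests(
        net, spm, n_perm=n_perm, seed=int(perm_label_seed.generate_state(1)[0] >> 1),
        kinds=kinds, bpm_pairs=bpm_pairs,
    )
    rng = np.random.default_rng(sample_perm_seed)
    perm_runs = []
    for r in range(n_sample_perm):
        pds = permute_phenotype(dataset, rng)
        pnet = build_interaction_network(pds, model, delta)
        ptable = run_block_tests(
            pnet, spm, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
            kinds=kinds, bpm_pairs=bpm_pairs,
        )
        perm_runs.append(ptable)
    results = sample_permutation_fdr(results, perm_runs)
    return DiscoveryResult(results, perm_runs, net, spm, model, delta)


def run_discovery(config: RunConfig) -> DiscoveryResult:
    """File-driven pipeline: import, QC, mapping, (pilot), discovery, FDR.

    Writes discovery tables, the QC report, permutation-run archives and a
    machine-readable manifest under ``config.out_dir``.
    """
    dataset, gene_map, pathways = pio.import_dataset(config.data_dir)
    qc_report: Optional[QCReport] = None
    if config.skip_qc:
        ds = dataset
    else:
        ds, qc_report = preprocess(dataset, config.qc, seed=config.seed)
    snp_gene = map_snps_to_genes(ds.snps, gene_map, config.mapping.window_bp)
    spm = build_snp_pathway_matrix(snp_gene, pathways, config.mapping,
                                   snp_ids=ds.snp_ids)
    pilot_table = None
    model, delta = config.model, config.delta
    if config.model == "pilot":
        model, delta, pilot_table = pilot_select_model(
            ds, spm, config.pilot_models, config.pilot_densities,
            n_perm_pilot=config.pilot_n_perm, seed=config.seed,
        )
        logger.info("pilot selected model=%s delta=%.3f", model, delta)
    result = run_interaction_discovery(
        ds, spm, model, delta, n_perm=config.n_perm,
        n_sample_perm=config.n_sample_perm, seed=config.seed,
    )
    result.qc_report = qc_report
    result.pilot_table = pilot_table
    sig = result.significant(config.fdr_report_threshold)
    nonred, _ = redundancy_filter(sig, spm, config.redundancy_overlap)
    result.nonredundant = nonred

    out = config.out_dir
    os.makedirs(os.path.join(out, "permutation_runs"), exist_ok=True)
    result.results.to_csv(os.path.join(out, "block_tests.tsv"), sep="\t",
                          index=False)
    sig.to_csv(os.path.join(out, "discoveries.tsv"), sep="\t", index=False)
    nonred.to_csv(os.path.join(out, "discoveries_nonredundant.tsv"), sep="\t",
                  index=False)
    if qc_report is not None:
        qc_report.to_frame().to_csv(os.path.join(out, "qc_report.tsv"),
                                    sep="\t", index=False)
    if pilot_table is not None:
        pilot_table.to_csv(os.path.join(out, "pilot.tsv"), sep="\t", index=False)
    for r, table in enumerate(result.permutation_runs):
        table.to_csv(
            os.path.join(out, "permutation_runs", f"perm{r:02d}.tsv"),
            sep="\t", index=False,
        )
    manifest = config.to_manifest()
    manifest.update(
        {
            "effective_model": model,
            "effective_delta": delta,
            "realized_density_risk": result.network.rho_risk,
            "realized_density_protective": result.network.rho_protective,
            "n_snps_analyzed": result.network.n_snps,
            "n_pathways_analyzed": spm.n_pathways,
        }
    )
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
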