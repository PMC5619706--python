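"""Text-format I/O: PLINK PED/MAP genotypes, gene tables, GMT gene sets.

All files are tab-delimited UTF-8; gene coordinates are 1-based inclusive.
A ``snps.tsv`` side table carries allele labels and the generating MAF so
that a dataset round-trips losslessly through PED/MAP (which do not store
allele frequencies).
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .datatypes import (
    MISSING,
    GeneRecord,
    GenotypeDataset,
    PathwayCollection,
    SNPRecord,
    TruthSet,
)

__all__ = [
    "export_dataset",
    "import_dataset",
    "read_gmt",
    "write_gmt",
    "read_gene_table",
    "write_gene_table",
    "write_truth_table",
]


def write_gmt(pathways: PathwayCollection, path: str) -> None:
    """GMT: pathway_id <tab> description <tab> gene ids, tab-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(pathways.sets):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{pid}\t{genes}\n")


def read_gmt(path: str) -> PathwayCollection:
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = frozenset(fields[2:])
    return PathwayCollection(sets)


def write_gene_table(genes: Sequence[GeneRecord], path: str) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start_bp, g.end_bp) for g in genes],
        columns=["gene_id", "chrom", "start_bp", "end_bp"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str) -> List[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRecord(r.gene_id, r.chrom, int(r.start_bp), int(r.end_bp))
        for r in df.itertuples()
    ]


def write_truth_table(truth: TruthSet, path: str) -> None:
    rows = []
    for eff in truth.effects:
        for i, j in eff.causal_pairs:
            rows.append(
                (
                    eff.kind,
                    eff.pathway_a,
                    eff.pathway_b or ".",
                    eff.coding,
                    eff.direction,
                    eff.effect_log_odds,
                    i,
                    j,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "kind",
            "pathway_a",
            "pathway_b",
            "coding",
            "direction",
            "effect_log_odds",
            "snp_i",
            "snp_j",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_ped_map(dataset: GenotypeDataset, prefix: str) -> None:
    with open(prefix + ".map", "w", encoding="utf-8") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    minor = [s.minor_allele for s in dataset.snps]
    major = [s.major_allele for s in dataset.snps]
    with open(prefix + ".ped", "w", encoding="utf-8") as fh:
        for row, sid, pheno in zip(
            dataset.dosage, dataset.sample_ids, dataset.phenotype
        ):
            # PLINK phenotype coding: 2 = case, 1 = control
            fields = [sid, sid, "0", "0", "0", str(int(pheno) + 1)]
            for d, a, b in zip(row, minor, major):
                if d == MISSING:
                    fields.append("0 0")
                elif d == 0:
                    fields.append(f"{b} {b}")
                elif d == 1:
                    fields.append(f"{a} {b}")
                else:
                    fields.append(f"{a} {a}")
            fh.write("\t".join(fields) + "\n")


def _write_snp_table(dataset: GenotypeDataset, path: str) -> None:
    pd.DataFrame(
        [
            (s.snp_id, s.chrom, s.pos_bp, s.minor_allele, s.major_allele, s.maf)
            for s in dataset.snps
        ],
        columns=["snp_id", "chrom", "pos_bp", "minor_allele", "major_allele", "maf"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def export_dataset(
    dataset: GenotypeDataset,
    gene_map: Sequence[GeneRecord],
    pathways: PathwayCollection,
    out_dir: str,
    truth: Optional[TruthSet] = None,
) -> None:
    """Write genotypes.ped/.map, snps.tsv, genes.tsv, pathways.gmt (+ truth)."""
    os.makedirs(out_dir, exist_ok=True)
    try:
        _write_ped_map(dataset, os.path.join(out_dir, "genotypes"))
        _write_snp_table(dataset, os.path.join(out_dir, "snps.tsv"))
        write_gene_table(gene_map, os.path.join(out_dir, "genes.tsv"))
        write_gmt(pathways, os.path.join(out_dir, "pathways.gmt"))
        if truth is not None:
            write_truth_table(truth, os.path.join(out_dir, "truth.tsv"))
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out_dir!r}: {exc}") from exc


def import_dataset(
    in_dir: str,
) -> Tuple[GenotypeDataset, List[GeneRecord], PathwayCollection]:
    """Read back a dataset written by :func:`export_dataset`."""
    prefix = os.path.join(in_dir, "genotypes")
    snp_df = pd.read_csv(os.path.join(in_dir, "snps.tsv"), sep="\t",
                         dtype={"chrom": str}, float_precision="round_trip")
    snps = [
        SNPRecord(r.snp_id, r.chrom, int(r.pos_bp), r.minor_allele, r.major_allele, r.maf)
        for r in snp_df.itertuples()
    ]
    map_ids = []
    with open(prefix + ".map", encoding="utf-8") as fh:
        for line in fh:
            map_ids.append(line.split("\t")[1])
    if map_ids != [s.snp_id for s in snps]:
        raise ValueError(f"{prefix}.map SNP order disagrees with snps.tsv")
    minor = {s.snp_id: s.minor_allele for s in snps}
    sample_ids: List[str] = []
    phenos: List[int] = []
    rows: List[List[int]] = []
    with open(prefix + ".ped", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            sample_ids.append(fields[1])
            phenos.append(int(fields[5]) - 1)
            row = []
            for sid, geno in zip(map_ids, fields[6:]):
                a, b = geno.split(" ")
                if a == "0" or b == "0":
                    row.append(MISSING)
                else:
                    row.append((a == minor[sid]) + (b == minor[sid]))
            rows.append(row)
    import numpy as np

    dataset = GenotypeDataset(snps, sample_ids, np.array(rows, dtype=np.int8),
                              np.array(phenos, dtype=np.int8))
    genes = read_gene_table(os.path.join(in_dir, "genes.tsv"))
    pathways = read_gmt(os.path.join(in_dir, "pathways.gmt"))
    return dataset, genes, pathways
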