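"""SNP-to-gene window mapping and the SNP x pathway membership matrix.

A SNP maps to every gene whose body overlaps a +/- ``window_bp`` window
centered at the SNP (closed intervals on both ends).  A pathway's SNP set
is the union of the SNPs of its genes; pathways are then filtered on both
a gene count and a SNP count.  The gene count is the number of the
pathway's genes with at least one mapped SNP, so both filters describe the
matrix that is actually analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneRecord, PathwayCollection, SNPRecord

__all__ = ["MappingConfig", "SNPPathwayMatrix", "map_snps_to_genes",
           "build_snp_pathway_matrix"]


@dataclass(frozen=True)
class MappingConfig:
    window_bp: int = 50_000
    min_genes: int = 10
    max_genes: int = 300
    min_snps: int = 10
    max_snps: int = 300

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.min_genes > self.max_genes or self.min_snps > self.max_snps:
            raise ValueError("min bound exceeds max bound")


def map_snps_to_genes(
    snps: Sequence[SNPRecord],
    gene_map: Sequence[GeneRecord],
    window_bp: int = 50_000,
) -> Dict[str, List[str]]:
    """snp_id -> sorted gene ids whose span intersects [pos-w, pos+w]."""
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in gene_map:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts = {}
    ends = {}
    names = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.start_bp)
        starts[chrom] = np.array([g.start_bp for g in genes])
        ends[chrom] = np.array([g.end_bp for g in genes])
        names[chrom] = [g.gene_id for g in genes]
    out: Dict[str, List[str]] = {}
    for s in snps:
        hits: List[str] = []
        if s.chrom in starts:
            lo, hi = s.pos_bp - window_bp, s.pos_bp + window_bp
            ok = (starts[s.chrom] <= hi) & (ends[s.chrom] >= lo)
            hits = sorted(np.array(names[s.chrom])[ok].tolist())
        out[s.snp_id] = hits
    return out


class SNPPathwayMatrix:
    """Binary SNP-to-pathway membership after mapping and size filtering."""

    def __init__(
        self,
        snp_ids: Sequence[str],
        pathway_ids: Sequence[str],
        membership: np.ndarray,
        gene_counts: Dict[str, int],
        snp_gene_map: Dict[str, List[str]],
        removed: Dict[str, str],
    ) -> None:
        membership = np.asarray(membership, dtype=bool)
        if membership.shape != (len(snp_ids), len(pathway_ids)):
            raise ValueError("membership shape mismatch")
        self.snp_ids = list(snp_ids)
        self.pathway_ids = list(pathway_ids)
        self.membership = membership
        self.gene_counts = dict(gene_counts)
        self.snp_gene_map = snp_gene_map
        self.removed = dict(removed)
        self._col = {p: k for k, p in enumerate(self.pathway_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def members(self, pathway_id: str) -> np.ndarray:
        """Indices (into snp_ids) of the pathway's SNPs."""
        return np.flatnonzero(self.membership[:, self._col[pathway_id]])

    def snp_counts(self) -> Dict[str, int]:
        return {p: int(self.membership[:, k].sum())
                for k, p in enumerate(self.pathway_ids)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.snp_ids[i], p)
            for k, p in enumerate(self.pathway_ids)
            for i in np.flatnonzero(self.membership[:, k])
        ]
        return pd.DataFrame(rows, columns=["snp_id", "pathway_id"])


def build_snp_pathway_matrix(
    snp_gene_map: Dict[str, List[str]],
    pathways: PathwayCollection,
    config: MappingConfig = MappingConfig(),
    snp_ids: Sequence[str] = None,
) -> SNPPathwayMatrix:
    """Union SNPs over each pathway's genes and apply both size filters.

    ``snp_ids`` fixes the SNP index order (defaults to the sorted keys of
    ``snp_gene_map``).  Pathways failing the gene-count or SNP-count
    bounds are dropped with a reason; an empty result is an error.
    """
    if snp_ids is None:
        snp_ids = sorted(snp_gene_map)
    idx = {s: i for i, s in enumerate(snp_ids)}
    gene_snps: Dict[str, List[int]] = {}
    for sid, genes in snp_gene_map.items():
        if sid not in idx:
            continue
        for g in genes:
            gene_snps.setdefault(g, []).append(idx[sid])
    kept_cols = []
    kept_ids = []
    gene_counts = {}
    removed: Dict[str, str] = {}
    for pid in sorted(pathways.sets):
        genes_with_snps = [g for g in pathways[pid] if g in gene_snps]
        snp_set = set()
        for g in genes_with_snps:
            snp_set.update(gene_snps[g])
        n_genes, n_snps = len(genes_with_snps), len(snp_set)
        if n_genes < config.min_genes:
            removed[pid] = "TOO_FEW_GENES"
        elif n_genes > config.max_genes:
            removed[pid] = "TOO_MANY_GENES"
        elif n_snps < config.min_snps:
            removed[pid] = "TOO_FEW_SNPS"
        elif n_snps > config.max_snps:
            removed[pid] = "TOO_MANY_SNPS"
        else:
            col = np.zeros(len(snp_ids), dtype=bool)
            col[sorted(snp_set)] = True
            kept_cols.append(col)
            kept_ids.append(pid)
            gene_counts[pid] = n_genes
    if not kept_ids:
        raise ValueError("no pathway passes the size filters")
    membership = np.stack(kept_cols, axis=1)
    return SNPPathwayMatrix(list(snp_ids), kept_ids, membership, gene_counts,
                            snp_gene_map, removed)
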