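"""Synthetic case-control cohorts with planted pathway-level interactions.

The generator emulates the inputs of a pathway-epistasis screen: biallelic
SNPs in Hardy-Weinberg proportions at configurable minor-allele
frequencies, genes laid out on a synthetic chromosome, curated-style gene
sets, and a binary phenotype assigned by a logistic model whose only
non-baseline terms are *joint* minor-allele-carrier indicators for planted
cross-pathway (or within-pathway) SNP pairs.  Because single-locus terms
are absent, any marginal association in the data arises solely through the
planted interactions -- the regime the pathway-level tests are built for.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    MISSING,
    GeneRecord,
    GenotypeDataset,
    PathwayCollection,
    PlantedEffect,
    SNPRecord,
    TruthSet,
)

__all__ = [
    "EffectConfig",
    "LDBlockConfig",
    "generate_pathway_universe",
    "generate_cohort",
]


@dataclass(frozen=True)
class EffectConfig:
    """Specification of one effect to plant.

    ``pair_fraction`` is the fraction of eligible SNP pairs of the block
    that become causal; each causal pair contributes ``effect_log_odds``
    (sign set by ``direction``) to a sample's disease log-odds when the
    sample carries the coded genotype at BOTH loci.
    """

    kind: str = "BPM"
    pathway_a: str = ""
    pathway_b: Optional[str] = None
    coding: str = "dominant"
    direction: str = "risk"
    effect_log_odds: float = np.log(3.0)
    pair_fraction: float = 0.3


@dataclass(frozen=True)
class LDBlockConfig:
    """Append LD proxies: copies of template SNPs with per-entry flip noise."""

    n_blocks: int = 0
    block_size: int = 3  # SNPs per block including the template
    flip_prob: float = 0.02


def generate_pathway_universe(
    n_genes: int,
    n_pathways: int,
    genes_per_pathway_range: Tuple[int, int],
    chrom_length_bp: int = 250_000_000,
    seed: int = 0,
    gene_length_bp: int = 20_000,
    gene_spacing_bp: int = 120_000,
    chrom: str = "1",
) -> Tuple[List[GeneRecord], PathwayCollection]:
    """Lay out non-overlapping genes and sample gene sets from them.

    Genes are placed on a single synthetic chromosome with a fixed
    inter-gene gap; the default gap (120 kb) exceeds twice the standard
    50 kb SNP-to-gene mapping window, so SNPs placed inside a gene map to
    that gene only.  Each pathway samples its genes without replacement
    (genes may be shared between pathways).
    """
    lo, hi = genes_per_pathway_range
    if not (1 <= lo <= hi):
        raise ValueError("genes_per_pathway_range must satisfy 1 <= lo <= hi")
    if hi > n_genes:
        raise ValueError(
            f"cannot sample up to {hi} genes per pathway from {n_genes} genes"
        )
    span = gene_length_bp + gene_spacing_bp
    needed = gene_spacing_bp + n_genes * span
    if needed > chrom_length_bp:
        raise ValueError(
            f"{n_genes} genes of {gene_length_bp} bp with {gene_spacing_bp} bp "
            f"gaps need {needed} bp > chromosome length {chrom_length_bp} bp"
        )
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        start = gene_spacing_bp + i * span + 1
        genes.append(
            GeneRecord(f"G{i + 1:05d}", chrom, start, start + gene_length_bp - 1)
        )
    gene_ids = np.array([g.gene_id for g in genes])
    sets: Dict[str, frozenset] = {}
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(gene_ids, size=size, replace=False)
        sets[f"PW{p + 1:04d}"] = frozenset(chosen.tolist())
    return genes, PathwayCollection(sets)


def _pathway_snp_ids(
    pathway: str, pathways: PathwayCollection, gene_snps: Dict[str, List[str]]
) -> List[str]:
    out: List[str] = []
    for g in sorted(pathways[pathway]):
        out.extend(gene_snps.get(g, []))
    return out


def _choose_causal_pairs(
    cfg: EffectConfig,
    pathways: PathwayCollection,
    gene_snps: Dict[str, List[str]],
    all_snp_ids: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[Tuple[str, str], ...]:
    a_snps = _pathway_snp_ids(cfg.pathway_a, pathways, gene_snps)
    if cfg.kind == "BPM":
        b_snps = _pathway_snp_ids(cfg.pathway_b, pathways, gene_snps)
        shared = set(a_snps) & set(b_snps)
        pool = [
            (i, j)
            for i in a_snps
            for j in b_snps
            if i not in shared and j not in shared
        ]
    elif cfg.kind == "WPM":
        pool = list(itertools.combinations(a_snps, 2))
    else:  # PATH: member SNPs paired with random non-member partners
        non_members = [s for s in all_snp_ids if s not in set(a_snps)]
        seen = set()
        pool = []
        for i in a_snps:
            for _ in range(3):  # a few genome-wide partners per member SNP
                pair = (i, str(rng.choice(non_members)))
                if pair not in seen:
                    seen.add(pair)
                    pool.append(pair)
    if not pool:
        raise ValueError(f"no eligible SNP pairs for planted effect on {cfg.pathway_a}")
    k = max(1, int(round(cfg.pair_fraction * len(pool))))
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    pairs = tuple(tuple(sorted(pool[i])) for i in sorted(idx))
    return pairs


def _carrier(dosage_col: np.ndarray, coding: str) -> np.ndarray:
    if coding == "recessive":
        return dosage_col == 2
    return dosage_col >= 1


def generate_cohort(
    gene_map: Sequence[GeneRecord],
    pathways: PathwayCollection,
    n_cases: int,
    n_controls: int,
    maf_range: Tuple[float, float] = (0.05, 0.45),
    truth: Sequence[EffectConfig] = (),
    missing_rate: float = 0.0,
    ld_block_config: Optional[LDBlockConfig] = None,
    snps_per_gene: int = 2,
    baseline_log_odds: float = 0.0,
    seed: int = 0,
) -> Tuple[GenotypeDataset, TruthSet]:
    """Simulate a case-control cohort with known planted truth.

    SNPs are placed evenly inside each gene body (``snps_per_gene`` per
    gene).  Null genotypes are drawn in Hardy-Weinberg proportions at a
    per-SNP MAF sampled uniformly from ``maf_range``.  Disease status is
    assigned by a logistic model: baseline log-odds plus, for every causal
    pair carried jointly under its planted coding, ``effect_log_odds``
    (negative for protective effects).  The liability is centered at the
    analytic mean planted load (from the per-SNP carrier probabilities),
    so ``baseline_log_odds`` is the disease log-odds of an average-load
    individual and the population prevalence stays near
    sigmoid(baseline_log_odds) however strong the planted effects are.
    Samples are drawn until the case and control quotas are filled, so
    class sizes are exact by construction.
    """
    if not (0.0 <= missing_rate < 0.2):
        raise ValueError("missing_rate must be in [0, 0.2)")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    for cfg in truth:
        if cfg.effect_log_odds <= 0:
            raise ValueError("effect_log_odds must be > 0")
        if cfg.pathway_a not in pathways.sets:
            raise ValueError(f"unknown pathway {cfg.pathway_a!r} in truth config")
        if cfg.kind == "BPM" and cfg.pathway_b not in pathways.sets:
            raise ValueError(f"unknown pathway {cfg.pathway_b!r} in truth config")
    rng = np.random.default_rng(seed)

    # --- SNP placement --------------------------------------------------
    snp_pos: List[Tuple[str, str, int]] = []  # (snp_id, chrom, pos)
    gene_snps: Dict[str, List[str]] = {}
    counter = 1
    for g in sorted(gene_map, key=lambda g: (g.chrom, g.start_bp)):
        length = g.end_bp - g.start_bp + 1
        ids = []
        for k in range(snps_per_gene):
            pos = g.start_bp + (k + 1) * length // (snps_per_gene + 1)
            sid = f"rs{counter:06d}"
            counter += 1
            snp_pos.append((sid, g.chrom, pos))
            ids.append(sid)
        gene_snps[g.gene_id] = ids
    snp_pos.sort(key=lambda t: (t[1], t[2]))
    snp_ids = [t[0] for t in snp_pos]
    m = len(snp_ids)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)

    # --- planted truth --------------------------------------------------
    effects: List[PlantedEffect] = []
    for cfg in truth:
        pairs = _choose_causal_pairs(cfg, pathways, gene_snps, snp_ids, rng)
        effects.append(
            PlantedEffect(
                kind=cfg.kind,
                pathway_a=cfg.pathway_a,
                pathway_b=cfg.pathway_b if cfg.kind == "BPM" else None,
                coding=cfg.coding,
                direction=cfg.direction,
                effect_log_odds=cfg.effect_log_odds,
                causal_pairs=pairs,
            )
        )
    truth_set = TruthSet(tuple(effects))
    col = {sid: k for k, sid in enumerate(snp_ids)}
    pair_cols = []  # (i, j, coding, signed beta)
    for eff in effects:
        beta = eff.effect_log_odds * (1 if eff.direction == "risk" else -1)
        for i, j in eff.causal_pairs:
            pair_cols.append((col[i], col[j], eff.coding, beta))

    # --- rejection-sample genotypes until class quotas are met ----------
    p_geno = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], axis=1)
    cum = np.cumsum(p_geno, axis=1)
    # center the liability at the analytic mean planted load
    carrier_prob = {"recessive": mafs**2, "dominant": 1.0 - (1.0 - mafs) ** 2}
    mean_load = sum(
        beta * carrier_prob[coding][i] * carrier_prob[coding][j]
        for i, j, coding, beta in pair_cols
    )
    case_rows: List[np.ndarray] = []
    ctrl_rows: List[np.ndarray] = []
    need_cases, need_ctrls = n_cases, n_controls
    batch = max(64, 2 * (n_cases + n_controls))
    for _ in range(200):
        if need_cases <= 0 and need_ctrls <= 0:
            break
        u = rng.random((batch, m))
        dos = (u[:, :] > cum[None, :, 0]).astype(np.int8) + (
            u[:, :] > cum[None, :, 1]
        ).astype(np.int8)
        logit = np.full(batch, baseline_log_odds - mean_load)
        for i, j, coding, beta in pair_cols:
            joint = _carrier(dos[:, i], coding) & _carrier(dos[:, j], coding)
            logit += beta * joint
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(batch) < p_case
        if need_cases > 0:
            take = np.flatnonzero(is_case)[:need_cases]
            case_rows.extend(dos[take])
            need_cases -= len(take)
        if need_ctrls > 0:
            take = np.flatnonzero(~is_case)[:need_ctrls]
            ctrl_rows.extend(dos[take])
            need_ctrls -= len(take)
    else:
        raise RuntimeError(
            "could not fill case/control quotas; planted effects may be too "
            "extreme for the configured baseline log-odds"
        )
    dosage = np.vstack([np.array(case_rows), np.array(ctrl_rows)])
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    order = rng.permutation(n_cases + n_controls)
    dosage = dosage[order]
    phenotype = phenotype[order]

    records = [
        SNPRecord(sid, chrom, pos, "a", "A", maf)
        for (sid, chrom, pos), maf in zip(snp_pos, mafs)
    ]

    # --- optional LD blocks ---------------------------------------------
    if ld_block_config is not None and ld_block_config.n_blocks > 0:
        cfg = ld_block_config
        templates = rng.choice(m, size=cfg.n_blocks, replace=False)
        extra_records = []
        extra_cols = []
        for t in sorted(templates):
            for k in range(1, cfg.block_size):
                base = dosage[:, t].copy()
                flip = rng.random(base.shape[0]) < cfg.flip_prob
                if flip.any():
                    u = rng.random(flip.sum())
                    resampled = (u > cum[t, 0]).astype(np.int8) + (
                        u > cum[t, 1]
                    ).astype(np.int8)
                    base[flip] = resampled
                r = records[t]
                extra_records.append(
                    SNPRecord(
                        f"{r.snp_id}_ld{k}", r.chrom, r.pos_bp + 10 * k, "a", "A", r.maf
                    )
                )
                extra_cols.append(base)
        records = records + extra_records
        dosage = np.hstack([dosage, np.stack(extra_cols, axis=1)])
        order2 = np.lexsort(
            ([r.snp_id for r in records], [r.pos_bp for r in records],
             [r.chrom for r in records])
        )
        records = [records[i] for i in order2]
        dosage = dosage[:, order2]

    # --- missingness -----------------------------------------------------
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage = dosage.copy()
        dosage[mask] = MISSING

    sample_ids = [f"S{k + 1:05d}" for k in range(n_cases + n_controls)]
    dataset = GenotypeDataset(records, sample_ids, dosage, phenotype)
    return dataset, truth_set
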