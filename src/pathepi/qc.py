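"""Sample and SNP quality control for case-control genotype data.

The filtering order is fixed: samples with excess missingness are removed
first, then SNP filters (missingness, MAF, Hardy-Weinberg) are computed on
the surviving samples.  MAF is computed over non-missing calls in all
surviving samples; the HWE exact test is computed in controls only, the
standard GWAS convention (a disease association itself distorts genotype
proportions in cases).  All thresholds are strict inequalities: a SNP with
MAF exactly at the minimum is retained.

Relatedness uses the PLINK-style method-of-moments PI_HAT estimator from
identity-by-state counts; LD pruning is a greedy sliding-window r^2 filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datatypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "hwe_exact_test",
    "qc_filter",
    "estimate_relatedness",
    "remove_related",
    "ld_prune",
    "match_case_control",
]


@dataclass(frozen=True)
class QCConfig:
    max_sample_missing: float = 0.05
    max_snp_missing: float = 0.05
    min_maf: float = 0.05
    hwe_p_threshold: float = 1.0e-6
    max_ibd: float = 0.2
    ld_r2_threshold: float = 0.1
    ld_window_snps: int = 50
    ld_step_snps: int = 5

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_snp_missing", "min_maf",
                     "hwe_p_threshold", "max_ibd", "ld_r2_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-step removal lists with reason codes and before/after counts."""

    steps: List[Dict] = field(default_factory=list)

    def add(self, reason: str, removed: List[str], n_before: int) -> None:
        self.steps.append(
            {
                "reason": reason,
                "removed": list(removed),
                "n_before": n_before,
                "n_after": n_before - len(removed),
            }
        )

    def removed_ids(self, reason: str) -> List[str]:
        for step in self.steps:
            if step["reason"] == reason:
                return step["removed"]
        return []

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s["reason"], rid) for s in self.steps for rid in s["removed"]
        ]
        return pd.DataFrame(rows, columns=["reason", "id"])


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the total genotype count and minor-allele count and sums
    the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count.  Monomorphic
    input yields p = 1 by convention.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # alleles mislabeled; fold to the rarer one
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    # support: heterozygote counts with the parity of n_minor
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # log P(het | n, n_minor) up to a constant: multinomial x 2^het
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(hets, n_het)]
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def _genotype_counts_controls(dataset: GenotypeDataset) -> np.ndarray:
    d = dataset.dosage[~dataset.case_mask]
    return np.stack([(d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0)],
                    axis=1)


def _qc_pass(ds: GenotypeDataset, config: QCConfig, report: QCReport
             ) -> Tuple[GenotypeDataset, int]:
    n_removed = 0
    # 1. sample missingness
    frac = ds.sample_missing_fraction()
    keep = frac <= config.max_sample_missing
    removed = [sid for sid, k in zip(ds.sample_ids, keep) if not k]
    report.add("SAMPLE_MISSING", removed, ds.n_samples)
    if not keep.any():
        raise ValueError("all samples removed by missingness filter")
    if removed:
        ds = ds.subset(sample_idx=np.flatnonzero(keep))
        n_removed += len(removed)
    if not ds.case_mask.any() or ds.case_mask.all():
        raise ValueError("missingness filter removed every case or every control")

    # 2. SNP missingness
    keep = ds.snp_missing_fraction() <= config.max_snp_missing
    removed = [sid for sid, k in zip(ds.snp_ids, keep) if not k]
    report.add("SNP_MISSING", removed, ds.n_snps)
    if removed:
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        n_removed += len(removed)

    # 3. MAF (all surviving samples, non-missing calls)
    maf = ds.observed_maf()
    keep = ~(np.nan_to_num(maf, nan=0.0) < config.min_maf)
    removed = [sid for sid, k in zip(ds.snp_ids, keep) if not k]
    report.add("SNP_MAF", removed, ds.n_snps)
    if removed:
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        n_removed += len(removed)

    # 4. HWE exact test in controls
    counts = _genotype_counts_controls(ds)
    pvals = np.array([hwe_exact_test(*c) for c in counts])
    keep = ~(pvals < config.hwe_p_threshold)
    removed = [sid for sid, k in zip(ds.snp_ids, keep) if not k]
    report.add("SNP_HWE", removed, ds.n_snps)
    if removed:
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        n_removed += len(removed)
    if ds.n_snps == 0:
        raise ValueError("all SNPs removed by QC filters")
    return ds, n_removed


def qc_filter(dataset: GenotypeDataset, config: QCConfig = QCConfig()
              ) -> Tuple[GenotypeDataset, QCReport]:
    """Apply sample-missingness, SNP-missingness, MAF and HWE filters.

    The pass (samples first, then SNP filters recomputed on the survivors)
    is iterated to a fixed point: removing a high-missingness SNP changes
    the surviving samples' missing fractions, so a single pass would not
    be idempotent.  Convergence is fast (usually one extra pass).
    """
    report = QCReport()
    ds = dataset
    for _ in range(20):
        ds, n_removed = _qc_pass(ds, config, report)
        if n_removed == 0:
            break
    else:  # pragma: no cover - pathological non-convergence
        raise RuntimeError("QC filtering did not converge")
    # merge per-reason removal lists accumulated over passes
    merged = QCReport()
    for reason in ("SAMPLE_MISSING", "SNP_MISSING", "SNP_MAF", "SNP_HWE"):
        ids: List[str] = []
        n_before = None
        for step in report.steps:
            if step["reason"] == reason:
                if n_before is None:
                    n_before = step["n_before"]
                ids.extend(step["removed"])
        merged.add(reason, ids, n_before or 0)
    return ds, merged


def estimate_relatedness(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise PI_HAT (proportion IBD) by PLINK-style method of moments.

    Uses observed IBS0/IBS1/IBS2 counts against their allele-frequency
    expectations under IBD state 0/1; missing genotypes drop a SNP from
    the affected pair only.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    if dataset.n_snps < 50:
        warnings.warn(
            f"only {dataset.n_snps} SNPs available; PI_HAT estimates are unstable",
            stacklevel=2,
        )
    d = dataset.dosage
    valid = (d != MISSING)
    p = dataset.observed_maf()
    p = np.nan_to_num(p, nan=0.0)
    q = 1.0 - p
    # per-SNP expectations conditional on IBD state
    e_i0_z0 = 2 * p**2 * q**2
    e_i1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_i1_z1 = 2 * p**2 * q + 2 * p * q**2
    A = [(valid & (d == k)).astype(np.float32) for k in (0, 1, 2)]
    V = valid.astype(np.float32)
    ibs2 = sum(a @ a.T for a in A)
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    n_obs = V @ V.T
    ibs1 = n_obs - ibs2 - ibs0
    E0 = (V * e_i0_z0) @ V.T
    E1z0 = (V * e_i1_z0) @ V.T
    E1z1 = (V * e_i1_z1) @ V.T
    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = np.where(E0 > 0, ibs0 / E0, 0.0)
        z1 = np.where(E1z1 > 0, (ibs1 - z0 * E1z0) / E1z1, 0.0)
    z0 = np.clip(z0, 0.0, 1.0)
    z1 = np.clip(z1, 0.0, 1.0 - z0)
    z2 = 1.0 - z0 - z1
    pi_hat = z2 + 0.5 * z1
    np.fill_diagonal(pi_hat, 1.0)
    return pi_hat.astype(np.float64)


def remove_related(dataset: GenotypeDataset, max_ibd: float = 0.2
                   ) -> Tuple[GenotypeDataset, List[str]]:
    """Drop one member of each pair with PI_HAT > max_ibd.

    The member with more missing genotypes is removed; ties go to the
    lexicographically larger sample id, making removal deterministic.
    """
    pi_hat = estimate_relatedness(dataset)
    miss = dataset.missing_mask().sum(axis=1)
    ids = dataset.sample_ids
    flagged = np.argwhere(np.triu(pi_hat > max_ibd, k=1))
    flagged = sorted(flagged.tolist(), key=lambda ij: (ids[ij[0]], ids[ij[1]]))
    removed: set = set()
    for i, j in flagged:
        if i in removed or j in removed:
            continue
        if miss[i] != miss[j]:
            drop = i if miss[i] > miss[j] else j
        else:
            drop = i if ids[i] > ids[j] else j
        removed.add(drop)
    keep = np.setdiff1d(np.arange(dataset.n_samples), sorted(removed))
    removed_ids = [ids[i] for i in sorted(removed)]
    if removed_ids:
        logger.info("relatedness filter removed %d samples", len(removed_ids))
        dataset = dataset.subset(sample_idx=keep)
    return dataset, removed_ids


def _pairwise_r2(cols: np.ndarray) -> np.ndarray:
    """r^2 between dosage columns, pairwise-complete over non-missing calls.

    Vectorized through matrix products of the zero-filled data and the
    validity mask; zero-variance pairs get r^2 = 0.
    """
    valid = (cols != MISSING)
    x = np.where(valid, cols, 0).astype(np.float64)
    v = valid.astype(np.float64)
    n = v.T @ v
    sx = x.T @ v  # sum of x_a over samples valid at both a and b
    sxx = (x * x).T @ v
    sxy = x.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sx.T
        var_a = n * sxx - sx**2
        denom = var_a * var_a.T
        r2 = np.where((denom > 0) & (n >= 2), cov**2 / denom, 0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(dataset: GenotypeDataset, config: QCConfig = QCConfig()) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Windows of ``ld_window_snps`` SNPs advance by ``ld_step_snps`` within
    each chromosome; inside a window the later SNP of any pair with
    r^2 > ``ld_r2_threshold`` is removed.
    """
    order = [(s.chrom, s.pos_bp) for s in dataset.snps]
    if order != sorted(order):
        raise ValueError("SNPs must be sorted by (chrom, pos) before LD pruning")
    removed = np.zeros(dataset.n_snps, dtype=bool)
    chroms = np.array([s.chrom for s in dataset.snps])
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), config.ld_step_snps):
            window = idx[start:start + config.ld_window_snps]
            window = window[~removed[window]]
            if len(window) < 2:
                if start + config.ld_window_snps >= len(idx):
                    break
                continue
            r2 = _pairwise_r2(dataset.dosage[:, window])
            for a in range(len(window)):
                if removed[window[a]]:
                    continue
                for b in range(a + 1, len(window)):
                    if removed[window[b]]:
                        continue
                    if r2[a, b] > config.ld_r2_threshold:
                        removed[window[b]] = True
            if start + config.ld_window_snps >= len(idx):
                break
    return np.flatnonzero(~removed)


def match_case_control(dataset: GenotypeDataset, seed: int = 0) -> GenotypeDataset:
    """Balance class sizes by seeded uniform downsampling of the larger class."""
    cases = np.flatnonzero(dataset.case_mask)
    ctrls = np.flatnonzero(~dataset.case_mask)
    if len(cases) == len(ctrls):
        return dataset
    rng = np.random.default_rng(seed)
    n = min(len(cases), len(ctrls))
    if len(cases) > n:
        cases = np.sort(rng.choice(cases, size=n, replace=False))
    else:
        ctrls = np.sort(rng.choice(ctrls, size=n, replace=False))
    keep = np.sort(np.concatenate([cases, ctrls]))
    return dataset.subset(sample_idx=keep)
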