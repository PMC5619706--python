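"""Core containers for case-control genotype data and pathway annotations.

Genotypes are stored as minor-allele dosage (0, 1, 2) with ``MISSING``
(-1) as the sentinel for no-calls.  Phenotypes are binary: 1 = case,
0 = control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

#: Sentinel for a missing genotype call (kept outside the dosage set {0,1,2}).
MISSING: int = -1

_ALLOWED_DOSAGES = frozenset({0, 1, 2, MISSING})


@dataclass(frozen=True)
class SNPRecord:
    """Identity and annotation of one biallelic SNP."""

    snp_id: str
    chrom: str
    pos_bp: int
    minor_allele: str
    major_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.snp_id}: minor and major allele identical")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (GMT-style): pathway_id -> frozenset of gene ids."""

    sets: Dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pathway_id: str) -> FrozenSet[str]:
        return self.sets[pathway_id]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


class GenotypeDataset:
    """Samples x SNPs minor-allele dosage matrix with binary phenotype.

    Parameters
    ----------
    snps:
        SNP metadata, one record per column of ``dosage``.
    sample_ids:
        One id per row of ``dosage``.
    dosage:
        int8 array of shape (n_samples, n_snps) with entries in
        {0, 1, 2, MISSING}.
    phenotype:
        int8 array of per-sample labels, 1 = case, 0 = control.
    """

    def __init__(
        self,
        snps: Sequence[SNPRecord],
        sample_ids: Sequence[str],
        dosage: np.ndarray,
        phenotype: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int8)
        phenotype = np.asarray(phenotype, dtype=np.int8)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if dosage.shape != (len(sample_ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(sample_ids)} samples x {len(snps)} SNPs"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage contains entries outside {0, 1, 2, MISSING}")
        if not np.isin(phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary (0 = control, 1 = case)")
        if phenotype.shape != (len(sample_ids),):
            raise ValueError("phenotype length does not match sample_ids")
        if not (phenotype == 1).any() or not (phenotype == 0).any():
            raise ValueError("dataset needs at least one case and one control")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids must be unique")
        self.snps: List[SNPRecord] = list(snps)
        self.sample_ids: List[str] = list(sample_ids)
        self.dosage = dosage
        self.phenotype = phenotype

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> List[str]:
        return [s.snp_id for s in self.snps]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    # -- derived per-SNP summaries ---------------------------------------

    def snp_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def observed_maf(self) -> np.ndarray:
        """Minor-allele frequency over non-missing calls, folded to <= 0.5."""
        d = self.dosage
        ok = d != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(ok, d, 0).sum(axis=0) / np.maximum(n_alleles, 1)
        freq = np.where(n_alleles == 0, np.nan, freq)
        return np.minimum(freq, 1.0 - freq)

    # -- subsetting -------------------------------------------------------

    def subset(
        self,
        sample_idx: Optional[np.ndarray] = None,
        snp_idx: Optional[np.ndarray] = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given row/column indices."""
        if sample_idx is None:
            sample_idx = np.arange(self.n_samples)
        if snp_idx is None:
            snp_idx = np.arange(self.n_snps)
        sample_idx = np.asarray(sample_idx)
        snp_idx = np.asarray(snp_idx)
        return GenotypeDataset(
            [self.snps[i] for i in snp_idx],
            [self.sample_ids[i] for i in sample_idx],
            self.dosage[np.ix_(sample_idx, snp_idx)],
            self.phenotype[sample_idx],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.snps == other.snps
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.phenotype, other.phenotype)
        )


@dataclass(frozen=True)
class PlantedEffect:
    """One planted pathway-level interaction with its causal SNP pairs."""

    kind: str  # 'BPM' | 'WPM' | 'PATH'
    pathway_a: str
    pathway_b: Optional[str]
    coding: str  # 'recessive' | 'dominant'
    direction: str  # 'risk' | 'protective'
    effect_log_odds: float
    causal_pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("BPM", "WPM", "PATH"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.coding not in ("recessive", "dominant"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.direction not in ("risk", "protective"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.effect_log_odds <= 0:
            raise ValueError("effect_log_odds must be > 0 (direction carries the sign)")


@dataclass(frozen=True)
class TruthSet:
    """All effects planted into a synthetic cohort (empty = pure null)."""

    effects: Tuple[PlantedEffect, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.effects)
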