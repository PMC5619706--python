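"""Pathway-block enrichment tests on a thresholded interaction network.

Three block kinds are tested on each network side (risk / protective):

* BPM -- between-pathway: the pair universe is all cross-pathway SNP
  pairs, excluding SNPs shared by both pathways (self-interaction guard).
* WPM -- within-pathway: all unordered pairs inside one pathway.
* PATH -- hub pathway: member SNP degrees versus non-member degrees,
  by a one-tailed rank-sum test.

Each BPM/WPM block gets three significance measures: chi2_global (edge
density versus the whole network), chi2_local (versus the stronger of the
two pathways' marginal densities; enrichment-only, one-tailed), and p_perm
from a SNP-label permutation null.  One shuffle of the SNP labels
reassigns every pathway's membership simultaneously, so a block's null
distribution depends only on its membership sizes; nulls are therefore
cached per size signature and shared across same-sized blocks, which is
what makes large permutation counts affordable.  PATH blocks get the
rank-sum p and a p_perm on mean member degree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import SNPPathwayMatrix
from .network import InteractionNetwork, snp_degree

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSpec",
    "block_id",
    "density_chi2_global",
    "density_chi2_local",
    "path_ranksum_test",
    "PermutationEngine",
    "run_block_tests",
]

SIDES = ("risk", "protective")
KINDS = ("BPM", "WPM", "PATH")


@dataclass(frozen=True)
class BlockSpec:
    """One tested block: a pathway pair (BPM) or single pathway (WPM/PATH)."""

    kind: str
    pathway_a: str
    pathway_b: Optional[str]
    side: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if (self.kind == "BPM") != (self.pathway_b is not None):
            raise ValueError("pathway_b must be given exactly for BPM blocks")


def block_id(kind: str, pathway_a: str, pathway_b: Optional[str], side: str) -> str:
    if pathway_b is not None:
        pathway_a, pathway_b = sorted((pathway_a, pathway_b))
    return f"{kind}|{pathway_a}|{pathway_b or '.'}|{side}"


def _exclusive_members(spm: SNPPathwayMatrix, pa: str, pb: str
                       ) -> Tuple[np.ndarray, np.ndarray]:
    a = spm.members(pa)
    b = spm.members(pb)
    shared = np.intersect1d(a, b)
    return np.setdiff1d(a, shared), np.setdiff1d(b, shared)


def _observed_bpm(adj: np.ndarray, a: np.ndarray, b: np.ndarray) -> Tuple[int, int]:
    t = len(a) * len(b)
    o = int(adj[np.ix_(a, b)].sum())
    return o, t


def _observed_wpm(adj: np.ndarray, a: np.ndarray) -> Tuple[int, int]:
    t = len(a) * (len(a) - 1) // 2
    o = int(adj[np.ix_(a, a)].sum()) // 2
    return o, t


def density_chi2_global(o: int, t: int, k_edges: int, tot_pairs: int) -> float:
    """Pearson chi-square of block density against global density.

    One-tailed for enrichment: returns 0 when the block density does not
    exceed the global density.  A zero expected cell yields 0 with a
    warning.
    """
    if t < 1:
        raise ValueError("INVALID_BLOCK: empty pair universe")
    if o / t <= k_edges / tot_pairs:
        return 0.0
    table = np.array(
        [[o, t - o], [k_edges - o, (tot_pairs - t) - (k_edges - o)]], dtype=float
    )
    row = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = row * colsum / tot_pairs
    if (expected == 0).any():
        warnings.warn("zero expected cell in chi2_global; returning 0", stacklevel=2)
        return 0.0
    return float(((table - expected) ** 2 / expected).sum())


def density_chi2_local(o: int, t: int, lam: float) -> float:
    """One-sample chi-square of block edges against the marginal rate lam."""
    if t < 1:
        raise ValueError("INVALID_BLOCK: empty pair universe")
    if lam <= 0.0 or lam >= 1.0:
        warnings.warn("degenerate marginal density in chi2_local; returning 0",
                      stacklevel=2)
        return 0.0
    if o <= lam * t:
        return 0.0
    exp_in = lam * t
    exp_out = (1.0 - lam) * t
    return float((o - exp_in) ** 2 / exp_in + ((t - o) - exp_out) ** 2 / exp_out)


def _marginal_density(adj: np.ndarray, members: np.ndarray, degrees: np.ndarray
                      ) -> float:
    """Edges touching the member set over pairs touching the member set."""
    m = adj.shape[0]
    k = len(members)
    if k == 0:
        return 0.0
    pairs_touching = m * (m - 1) // 2 - (m - k) * (m - k - 1) // 2
    within = int(adj[np.ix_(members, members)].sum()) // 2
    touching = int(degrees[members].sum()) - within
    return touching / pairs_touching if pairs_touching else 0.0


def path_ranksum_test(degrees: np.ndarray, member_mask: np.ndarray
                      ) -> Tuple[float, float]:
    """One-tailed Mann-Whitney U: member degrees stochastically larger.

    Exact enumeration when both groups have <= 12 SNPs and there are no
    ties; otherwise the normal approximation with tie correction (no
    continuity correction, so identical groups give p = 0.5).
    """
    member_mask = np.asarray(member_mask, dtype=bool)
    x = np.asarray(degrees)[member_mask]
    y = np.asarray(degrees)[~member_mask]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need at least one member and one non-member SNP")
    pooled = np.concatenate([x, y])
    if (pooled == pooled[0]).all():
        logger.info("degenerate rank-sum input (all degrees identical); p = 0.5")
        return float(len(x) * len(y) / 2), 0.5
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


class PermutationEngine:
    """Shared SNP-label permutations with size-indexed null caches.

    One instance holds ``n_perm`` random permutations of the SNP index;
    for a size signature it slices disjoint index blocks out of each
    permutation, exactly as one label shuffle induces all permuted
    pathway memberships at once.
    """

    def __init__(self, n_snps: int, n_perm: int, seed: int) -> None:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        self.n_perm = n_perm
        self.perms = np.argsort(rng.random((n_perm, n_snps)), axis=1)
        self._cache: Dict[Tuple, np.ndarray] = {}

    def null_bpm_density(self, adj: np.ndarray, size_a: int, size_b: int
                         ) -> np.ndarray:
        a, b = sorted((size_a, size_b))
        key = ("BPM", id(adj), a, b)
        if key not in self._cache:
            A = self.perms[:, :a]
            B = self.perms[:, a:a + b]
            m = adj.shape[0]
            flat = (A[:, :, None] * m + B[:, None, :]).reshape(self.n_perm, -1)
            counts = adj.ravel()[flat].sum(axis=1)
            self._cache[key] = counts / (a * b)
        return self._cache[key]

    def null_wpm_density(self, adj: np.ndarray, size_a: int) -> np.ndarray:
        key = ("WPM", id(adj), size_a)
        if key not in self._cache:
            A = self.perms[:, :size_a]
            m = adj.shape[0]
            flat = (A[:, :, None] * m + A[:, None, :]).reshape(self.n_perm, -1)
            counts = adj.ravel()[flat].sum(axis=1) / 2
            t = size_a * (size_a - 1) // 2
            self._cache[key] = counts / max(t, 1)
        return self._cache[key]

    def null_path_mean_degree(self, degrees: np.ndarray, size_a: int) -> np.ndarray:
        key = ("PATH", id(degrees), size_a)
        if key not in self._cache:
            A = self.perms[:, :size_a]
            self._cache[key] = degrees[A].mean(axis=1)
        return self._cache[key]


def _p_perm(null: np.ndarray, observed: float) -> float:
    if observed <= 0:
        return 1.0
    return float((1 + (null >= observed - 1e-12).sum()) / (1 + len(null)))


def run_block_tests(
    network: InteractionNetwork,
    spm: SNPPathwayMatrix,
    n_perm: int = 2000,
    seed: int = 0,
    kinds: Sequence[str] = KINDS,
    sides: Sequence[str] = SIDES,
    bpm_pairs: Optional[Iterable[Tuple[str, str]]] = None,
    engine: Optional[PermutationEngine] = None,
) -> pd.DataFrame:
    """Compute all block statistics and return one row per block.

    ``bpm_pairs`` restricts the BPM universe (e.g. to a focal pathway);
    the default is all unordered pathway pairs.
    """
    if spm.snp_ids != network.snp_ids:
        raise ValueError("SNP universe of membership matrix and network differ")
    m = network.n_snps
    tot_pairs = m * (m - 1) // 2
    if engine is None:
        engine = PermutationEngine(m, n_perm, seed)
    pathway_ids = spm.pathway_ids
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for side in sides:
            adj = network.adjacency(side)
            degrees = snp_degree(network, side)
            k_edges = int(degrees.sum()) // 2
            if "BPM" in kinds:
                if bpm_pairs is None:
                    pairs = [
                        (pathway_ids[i], pathway_ids[j])
                        for i in range(len(pathway_ids))
                        for j in range(i + 1, len(pathway_ids))
                    ]
                else:
                    pairs = [tuple(sorted(p)) for p in bpm_pairs]
                for pa, pb in pairs:
                    a, b = _exclusive_members(spm, pa, pb)
                    if len(a) == 0 or len(b) == 0:
                        continue
                    o, t = _observed_bpm(adj, a, b)
                    dens = o / t
                    chi_g = density_chi2_global(o, t, k_edges, tot_pairs)
                    lam = max(
                        _marginal_density(adj, a, degrees),
                        _marginal_density(adj, b, degrees),
                    )
                    chi_l = density_chi2_local(o, t, lam)
                    null = engine.null_bpm_density(adj, len(a), len(b))
                    rows.append(
                        (block_id("BPM", pa, pb, side), "BPM", pa, pb, side,
                         t, o, dens, chi_g, chi_l, _p_perm(null, dens),
                         np.nan, np.nan)
                    )
            if "WPM" in kinds:
                for pa in pathway_ids:
                    a = spm.members(pa)
                    if len(a) < 2:
                        continue
                    o, t = _observed_wpm(adj, a)
                    dens = o / t
                    chi_g = density_chi2_global(o, t, k_edges, tot_pairs)
                    lam = _marginal_density(adj, a, degrees)
                    chi_l = density_chi2_local(o, t, lam)
                    null = engine.null_wpm_density(adj, len(a))
                    rows.append(
                        (block_id("WPM", pa, None, side), "WPM", pa, None, side,
                         t, o, dens, chi_g, chi_l, _p_perm(null, dens),
                         np.nan, np.nan)
                    )
            if "PATH" in kinds:
                for pa in pathway_ids:
                    a = spm.members(pa)
                    if len(a) == 0 or len(a) == m:
                        continue
                    mask = np.zeros(m, dtype=bool)
                    mask[a] = True
                    u, p_rank = path_ranksum_test(degrees, mask)
                    obs = float(degrees[a].mean())
                    null = engine.null_path_mean_degree(degrees, len(a))
                    p_perm = _p_perm(null, obs)
                    rows.append(
                        (block_id("PATH", pa, None, side), "PATH", pa, None, side,
                         np.nan, np.nan, obs, np.nan, np.nan, p_perm, u, p_rank)
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "block_id", "kind", "pathway_a", "pathway_b", "side", "T", "O",
            "density", "chi2_global", "chi2_local", "p_perm",
            "ranksum_U", "ranksum_p",
        ],
    )
    # nominal p-values of the one-tailed chi-square statistics (1 df)
    df["chi2_global_p"] = np.where(
        df["kind"].eq("PATH"), np.nan, stats.chi2.sf(df["chi2_global"], df=1)
    )
    df["chi2_local_p"] = np.where(
        df["kind"].eq("PATH"), np.nan, stats.chi2.sf(df["chi2_local"], df=1)
    )
    return df
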