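"""Sample-permutation FDR, redundancy filtering and pilot model selection.

The false discovery rate of the ranked real results is estimated from
full reruns of the block tests under case-control label permutations:
for a result with rank key k, FDR(k) is the mean (over permutation runs)
count of permuted results at least as significant as k, divided by the
count of real results at least as significant, clipped to [0, 1] and
monotonized down the ranking.  Risk and protective directions -- and the
three block kinds -- are distinct hypothesis families and are estimated
separately.

The rank key orders results by (p_perm asc, chi2_global desc, chi2_local
desc); PATH blocks substitute the rank-sum evidence for the chi-squares.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset
from .mapping import SNPPathwayMatrix
from .block_tests import run_block_tests
from .network import build_interaction_network, score_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "rank_key_frame",
    "sample_permutation_fdr",
    "redundancy_filter",
    "pilot_select_model",
    "count_bpm_tests",
]

MODEL_PRECEDENCE = ("combined", "dominant", "recessive", "additive")


def rank_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Attach key1..key3 columns (all ascending = more significant first)."""
    out = df.copy()
    is_path = out["kind"].eq("PATH")
    out["key1"] = out["p_perm"]
    out["key2"] = np.where(is_path, out["ranksum_p"], -out["chi2_global"])
    out["key3"] = np.where(is_path, -out["ranksum_U"], -out["chi2_local"])
    return out


def _counts_at_least(real: np.ndarray, other: np.ndarray) -> np.ndarray:
    """For each real key row, #other rows with key <= it lexicographically.

    Keys are (n, 3) float arrays, ascending significance order.
    """
    if len(other) == 0:
        return np.zeros(len(real), dtype=int)
    order = np.lexsort((other[:, 2], other[:, 1], other[:, 0]))
    srt = other[order]
    counts = np.empty(len(real), dtype=int)
    for i, k in enumerate(real):
        lo, hi = 0, len(srt)
        # count rows with tuple <= k
        while lo < hi:
            mid = (lo + hi) // 2
            row = srt[mid]
            if tuple(row) <= tuple(k):
                lo = mid + 1
            else:
                hi = mid
        counts[i] = lo
    return counts


def sample_permutation_fdr(
    real_results: pd.DataFrame, permutation_runs: Sequence[pd.DataFrame]
) -> pd.DataFrame:
    """Attach an ``fdr`` column to the real results.

    Each permutation run must be a full block-test table computed under
    permuted case-control labels with settings identical to the real run.
    """
    if len(permutation_runs) == 0:
        raise ValueError("need at least one sample-permutation run")
    real = rank_key_frame(real_results).reset_index(drop=True)
    perms = [rank_key_frame(p) for p in permutation_runs]
    real["fdr"] = np.nan
    for (kind, side), idx in real.groupby(["kind", "side"]).groups.items():
        fam = real.loc[idx]
        keys = fam[["key1", "key2", "key3"]].to_numpy(dtype=float)
        n_real = _counts_at_least(keys, keys)
        perm_counts = np.zeros(len(fam))
        for p in perms:
            pf = p[(p["kind"] == kind) & (p["side"] == side)]
            pkeys = pf[["key1", "key2", "key3"]].to_numpy(dtype=float)
            perm_counts += _counts_at_least(keys, pkeys)
        perm_counts /= len(perms)
        fdr = np.clip(perm_counts / np.maximum(n_real, 1), 0.0, 1.0)
        # monotonize down-rank (running max in significance order)
        order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
        fdr_sorted = np.maximum.accumulate(fdr[order])
        out = np.empty_like(fdr)
        out[order] = fdr_sorted
        real.loc[idx, "fdr"] = out
    real = real.drop(columns=["key1", "key2", "key3"])
    return real.sort_values(["kind", "side", "fdr", "p_perm"]).reset_index(drop=True)


def _block_snp_sets(row: pd.Series, spm: SNPPathwayMatrix
                    ) -> Tuple[frozenset, Optional[frozenset]]:
    a = frozenset(spm.members(row["pathway_a"]).tolist())
    b = None
    if row["kind"] == "BPM":
        b = frozenset(spm.members(row["pathway_b"]).tolist())
    return a, b


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def redundancy_filter(
    discoveries: pd.DataFrame,
    spm: SNPPathwayMatrix,
    overlap_threshold: float = 0.25,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Collapse pathway-level results with heavily overlapping SNP sets.

    Two BPMs are redundant when their pathway pairs can be matched
    (directly or swapped) with Jaccard SNP-set overlap >= the threshold on
    BOTH sides; WPM/PATH compare their single pathway.  Groups are the
    transitive closure of pairwise redundancy within each (kind, side)
    family; the group representative is the member with the smallest
    p_perm (ties: larger chi2_global, then lexicographic block id).
    Returns the representative rows (with a ``redundancy_group`` column)
    and the block_id -> group map.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must be in (0, 1]")
    df = discoveries.reset_index(drop=True)
    sets = [_block_snp_sets(row, spm) for _, row in df.iterrows()]
    g = nx.Graph()
    g.add_nodes_from(range(len(df)))
    for i, j in combinations(range(len(df)), 2):
        ri, rj = df.iloc[i], df.iloc[j]
        if ri["kind"] != rj["kind"] or ri["side"] != rj["side"]:
            continue
        (ai, bi), (aj, bj) = sets[i], sets[j]
        if ri["kind"] == "BPM":
            direct = (_jaccard(ai, aj) >= overlap_threshold
                      and _jaccard(bi, bj) >= overlap_threshold)
            swapped = (_jaccard(ai, bj) >= overlap_threshold
                       and _jaccard(bi, aj) >= overlap_threshold)
            redundant = direct or swapped
        else:
            redundant = _jaccard(ai, aj) >= overlap_threshold
        if redundant:
            g.add_edge(i, j)
    group_of: Dict[str, int] = {}
    reps = []
    components = sorted(nx.connected_components(g),
                        key=lambda c: sorted(df.loc[list(c), "block_id"])[0])
    for gid, comp in enumerate(components):
        comp = list(comp)
        for i in comp:
            group_of[df.loc[i, "block_id"]] = gid
        ranked = sorted(
            comp,
            key=lambda i: (
                df.loc[i, "p_perm"],
                -np.nan_to_num(df.loc[i, "chi2_global"]),
                df.loc[i, "block_id"],
            ),
        )
        reps.append(ranked[0])
    out = df.loc[reps].copy()
    out["redundancy_group"] = [group_of[b] for b in out["block_id"]]
    out = out.sort_values(["kind", "side", "p_perm", "block_id"])
    return out.reset_index(drop=True), group_of


def pilot_select_model(
    dataset: GenotypeDataset,
    spm: SNPPathwayMatrix,
    models: Sequence[str],
    densities: Sequence[float],
    n_perm_pilot: int = 2000,
    seed: int = 0,
    default: Optional[Tuple[str, float]] = None,
) -> Tuple[str, float, pd.DataFrame]:
    """Pick the most sensitive (disease model, network density) pair.

    Sensitivity of a candidate is the number of blocks with p_perm <= 0.05
    in a reduced-permutation pilot run, minus the 5% expected by chance.
    Ties break by model precedence (combined > dominant > recessive >
    additive), then by smaller density.  If no candidate beats chance the
    configured default (first-precedence model, smallest density unless
    given) is returned with a warning -- the situation in which a cohort
    is not worth a full run.
    """
    if not models or not densities:
        raise ValueError("candidate model and density lists must be non-empty")
    rows = []
    for model in models:
        scores = score_pairs(dataset, model)
        for delta in densities:
            net = build_interaction_network(dataset, model, delta, scores=scores)
            table = run_block_tests(net, spm, n_perm=n_perm_pilot, seed=seed)
            n_sig = int((table["p_perm"] <= 0.05).sum())
            rows.append((model, delta, n_sig, len(table),
                         n_sig - 0.05 * len(table)))
    pilot = pd.DataFrame(
        rows, columns=["model", "delta", "n_sig", "n_blocks", "sensitivity"]
    )
    prec = {m: i for i, m in enumerate(MODEL_PRECEDENCE)}
    best = pilot.sort_values(
        ["sensitivity", "model", "delta"],
        ascending=[False, True, True],
        key=lambda s: s.map(prec) if s.name == "model" else s,
    ).iloc[0]
    if best["sensitivity"] <= 0:
        chosen = default or (
            sorted(models, key=lambda m: prec[m])[0], min(densities)
        )
        logger.warning(
            "pilot found no (model, density) more sensitive than chance; "
            "falling back to %s", chosen,
        )
        return chosen[0], chosen[1], pilot
    return str(best["model"]), float(best["delta"]), pilot


def count_bpm_tests(n_pathways: int, restricted_to_focal: bool = False) -> int:
    """Hypothesis count for BPM testing: both directions per pathway pair.

    Unrestricted: 2 * C(n, 2).  Restricted to one focal pathway: 2 * (n-1).
    """
    if n_pathways < 2:
        raise ValueError("need at least two pathways")
    if restricted_to_focal:
        return 2 * (n_pathways - 1)
    return n_pathways * (n_pathways - 1)
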