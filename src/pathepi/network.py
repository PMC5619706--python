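"""SNP-SNP interaction scoring and lenient-threshold binary networks.

Pair statistic
--------------
For a pair of SNPs under a disease-model coding (recessive: carrier iff
homozygous minor; dominant: carrier iff at least one minor allele), let
``joint`` be the samples carrying the coded genotype at BOTH loci.  With N
complete observations, C cases, n11 joint carriers of which c11 are cases,
the risk evidence is the hypergeometric upper tail P(X >= c11 | N, C, n11)
-- the one-sided Fisher p-value for case enrichment among joint carriers.
The pair scores only if this joint tail is strictly smaller than BOTH
single-SNP marginal tails (the same construction applied to each carrier
set alone): the score is -log10 of the joint tail, else 0.  This
marginality screen encodes "interaction beyond main effects".  Protective
scores are the identical construction with controls in the role of cases.

The combined model takes, per pair, the maximum over the four coding
assignments {RR, RD, DR, DD}.  The additive model scores a 2-df chi-square
of joint dosage (0+1 / 2 / 3+4 total minor alleles) against case status,
screened by the per-SNP 2-df dosage chi-squares.

Missing genotypes are handled pairwise-complete: a sample missing either
SNP is excluded from that pair's counts only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DISEASE_MODELS",
    "PairScoreMatrix",
    "InteractionNetwork",
    "encode_genotypes",
    "ssi_score_pair",
    "score_pairs",
    "build_interaction_network",
    "snp_degree",
]

DISEASE_MODELS = ("recessive", "dominant", "additive", "combined")


def hypergeom_sf_table(N: int, C: int) -> np.ndarray:
    """T[n, c] = P(X >= c) for X ~ Hypergeom(N, C, n), all n <= N, c <= C.

    Built from one log-pmf broadcast and a reverse cumulative sum; lookup
    is then O(1) per SNP pair, which is what makes scoring ~10^6 pairs per
    phenotype permutation cheap.
    """
    n = np.arange(N + 1)[:, None]
    c = np.arange(C + 1)[None, :]
    with np.errstate(invalid="ignore"):
        logpmf = (
            gammaln(C + 1) - gammaln(c + 1) - gammaln(C - c + 1)
            + gammaln(N - C + 1) - gammaln(n - c + 1) - gammaln(N - C - n + c + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
    invalid = (c > n) | (n - c > N - C)
    pmf = np.where(invalid, 0.0, np.exp(logpmf))
    sf = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(sf, 1.0)


def encode_genotypes(dataset: GenotypeDataset, coding: str
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Binary carrier matrix and validity mask for one disease-model coding."""
    if coding not in ("recessive", "dominant"):
        raise ValueError(f"coding must be recessive or dominant, got {coding!r}")
    d = dataset.dosage
    valid = d != MISSING
    if coding == "recessive":
        carrier = (d == 2)
    else:
        carrier = (d >= 1) & valid
    return carrier & valid, valid


def _tail_counts(x: np.ndarray, pheno: np.ndarray) -> Tuple[int, int]:
    return int(x.sum()), int(x[pheno == 1].sum())


def ssi_score_pair(
    carrier_i: np.ndarray,
    carrier_j: np.ndarray,
    phenotype: np.ndarray,
    valid_i: Optional[np.ndarray] = None,
    valid_j: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Reference per-pair scorer; returns (risk_score, protective_score)."""
    carrier_i = np.asarray(carrier_i, dtype=bool)
    carrier_j = np.asarray(carrier_j, dtype=bool)
    phenotype = np.asarray(phenotype)
    ok = np.ones(len(phenotype), dtype=bool)
    if valid_i is not None:
        ok &= np.asarray(valid_i, dtype=bool)
    if valid_j is not None:
        ok &= np.asarray(valid_j, dtype=bool)
    ci, cj, ph = carrier_i[ok], carrier_j[ok], phenotype[ok]
    N = int(ok.sum())
    C = int((ph == 1).sum())
    if C == 0 or C == N:
        raise ValueError("need at least one case and one control among complete samples")
    joint = ci & cj
    n11, c11 = _tail_counts(joint, ph)
    if n11 == 0:
        return 0.0, 0.0
    ni, c_i = _tail_counts(ci, ph)
    nj, c_j = _tail_counts(cj, ph)
    out = []
    for risk_side in (True, False):  # risk, then protective (controls as "cases")
        if risk_side:
            cases, k11, ki, kj = C, c11, c_i, c_j
        else:
            cases, k11, ki, kj = N - C, n11 - c11, ni - c_i, nj - c_j
        p_joint = float(stats.hypergeom.sf(k11 - 1, N, cases, n11))
        p_i = float(stats.hypergeom.sf(ki - 1, N, cases, ni))
        p_j = float(stats.hypergeom.sf(kj - 1, N, cases, nj))
        # relative epsilon so float noise cannot break an exact tie with a
        # marginal tail (ties are screened out, not scored)
        if p_joint < min(p_i, p_j) * (1.0 - 1e-9):
            out.append(-np.log10(p_joint))
        else:
            out.append(0.0)
    return out[0], out[1]


@dataclass
class PairScoreMatrix:
    """Symmetric -log10 pair evidence on the risk and protective sides."""

    snp_ids: List[str]
    risk: np.ndarray
    protective: np.ndarray
    model: str

    def __post_init__(self) -> None:
        for m in (self.risk, self.protective):
            if m.shape != (len(self.snp_ids), len(self.snp_ids)):
                raise ValueError("score matrix shape mismatch")


def _screened_scores_complete(
    Xa: np.ndarray, Xb: np.ndarray, case: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Scores for one ordered coding pair, no missing data (fast path).

    Xa/Xb: float32 carrier matrices (samples x SNPs) under coding a / b.
    Returns (risk, protective) with entry [i, j] scoring carrier-a at SNP i
    jointly with carrier-b at SNP j.
    """
    n_samples = Xa.shape[0]
    C = int(case.sum())
    n11 = np.rint(Xa.T @ Xb).astype(np.int64)
    c11 = np.rint(Xa[case].T @ Xb[case]).astype(np.int64)
    ni = np.rint(Xa.sum(axis=0)).astype(np.int64)
    ci = np.rint(Xa[case].sum(axis=0)).astype(np.int64)
    nj = np.rint(Xb.sum(axis=0)).astype(np.int64)
    cj = np.rint(Xb[case].sum(axis=0)).astype(np.int64)
    out = []
    for risk_side in (True, False):
        if risk_side:
            n_case, k11, ki, kj = C, c11, ci, cj
        else:
            n_case, k11, ki, kj = n_samples - C, n11 - c11, ni - ci, nj - cj
        table = hypergeom_sf_table(n_samples, n_case)
        p_joint = table[n11, k11]
        p_i = table[ni, ki][:, None]
        p_j = table[nj, kj][None, :]
        ok = (p_joint < np.minimum(p_i, p_j) * (1.0 - 1e-9)) & (n11 > 0)
        with np.errstate(divide="ignore"):
            s = np.where(ok, -np.log10(np.maximum(p_joint, 1e-300)), 0.0)
        np.fill_diagonal(s, 0.0)
        out.append(s)
    return out[0], out[1]


def _screened_scores_missing(
    Xa: np.ndarray, Xb: np.ndarray, V: np.ndarray, case: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete scores with missing data (general path)."""
    Vc = V[case]
    n = np.rint(V.T @ V).astype(np.int64)  # complete obs per pair
    cC = np.rint(Vc.T @ Vc).astype(np.int64)  # cases among them
    n11 = np.rint(Xa.T @ Xb).astype(np.int64)
    c11 = np.rint(Xa[case].T @ Xb[case]).astype(np.int64)
    ni = np.rint(Xa.T @ V).astype(np.int64)
    ci = np.rint(Xa[case].T @ Vc).astype(np.int64)
    nj = np.rint(V.T @ Xb).astype(np.int64)
    cj = np.rint(Vc.T @ Xb[case]).astype(np.int64)

    base = np.int64(n.max() + 1)

    def tails(k, nn, cases, draws):
        packed = (
            ((k.ravel().astype(np.int64) * base + nn.ravel()) * base
             + cases.ravel()) * base + draws.ravel()
        )
        uniq, inv = np.unique(packed, return_inverse=True)
        uk, rest = np.divmod(uniq, base * base * base)
        un, rest = np.divmod(rest, base * base)
        uc, ud = np.divmod(rest, base)
        p = stats.hypergeom.sf(uk - 1.0, un, uc, ud)
        return p[inv].reshape(k.shape)

    out = []
    for risk_side in (True, False):
        if risk_side:
            k11, ki, kj, cc = c11, ci, cj, cC
        else:
            k11, ki, kj, cc = n11 - c11, ni - ci, nj - cj, n - cC
        p_joint = tails(k11, n, cc, n11)
        p_i = tails(ki, n, cc, ni)
        p_j = tails(kj, n, cc, nj)
        ok = (p_joint < np.minimum(p_i, p_j) * (1.0 - 1e-9)) & (n11 > 0)
        with np.errstate(divide="ignore"):
            s = np.where(ok, -np.log10(np.maximum(p_joint, 1e-300)), 0.0)
        np.fill_diagonal(s, 0.0)
        out.append(s)
    return out[0], out[1]


def _coding_pair_scores(dataset: GenotypeDataset, coding_a: str, coding_b: str
                        ) -> Tuple[np.ndarray, np.ndarray]:
    Xa, V = encode_genotypes(dataset, coding_a)
    Xb, _ = encode_genotypes(dataset, coding_b)
    case = dataset.case_mask
    no_missing = not (dataset.dosage == MISSING).any()
    Xa32, Xb32 = Xa.astype(np.float32), Xb.astype(np.float32)
    if no_missing:
        return _screened_scores_complete(Xa32, Xb32, case)
    return _screened_scores_missing(Xa32, Xb32, V.astype(np.float32), case)


def _additive_scores(dataset: GenotypeDataset) -> Tuple[np.ndarray, np.ndarray]:
    """Screened 2-df chi-square on collapsed joint dosage (low/mid/high)."""
    d = dataset.dosage
    valid = d != MISSING
    case = dataset.case_mask
    D = [((d == k) & valid).astype(np.float32) for k in (0, 1, 2)]
    Dc = [x[case] for x in D]

    def class_counts(mats):
        # total dosage classes: {0,1} -> low, {2} -> mid, {3,4} -> high
        low = mats[0].T @ mats[0] + mats[0].T @ mats[1] + mats[1].T @ mats[0]
        mid = mats[0].T @ mats[2] + mats[2].T @ mats[0] + mats[1].T @ mats[1]
        high = mats[1].T @ mats[2] + mats[2].T @ mats[1] + mats[2].T @ mats[2]
        return np.stack([low, mid, high])

    tot = class_counts(D)
    cas = class_counts(Dc)
    con = tot - cas
    n = tot.sum(axis=0)
    n_case = cas.sum(axis=0)
    n_ctrl = con.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.zeros_like(n, dtype=float)
        for k in range(3):
            e_cas = n_case * tot[k] / n
            e_con = n_ctrl * tot[k] / n
            chi2 += np.where(e_cas > 0, (cas[k] - e_cas) ** 2 / e_cas, 0.0)
            chi2 += np.where(e_con > 0, (con[k] - e_con) ** 2 / e_con, 0.0)
    p_pair = stats.chi2.sf(chi2, df=2)
    # per-SNP marginal 2-df dosage chi-square for the screen
    p_marg = np.ones(dataset.n_snps)
    for s in range(dataset.n_snps):
        counts = np.array(
            [
                [(d[case, s] == k).sum() for k in (0, 1, 2)],
                [(d[~case, s] == k).sum() for k in (0, 1, 2)],
            ]
        )
        counts = counts[:, counts.sum(axis=0) > 0]
        if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
            continue
        p_marg[s] = stats.chi2_contingency(counts, correction=False)[1]
    screen = p_pair < np.minimum(p_marg[:, None], p_marg[None, :])
    # direction: case fraction in the high joint-dosage class vs overall
    with np.errstate(invalid="ignore"):
        high_case_frac = np.where(tot[2] > 0, cas[2] / tot[2], np.nan)
    overall = n_case / np.maximum(n, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(screen, -np.log10(np.maximum(p_pair, 1e-300)), 0.0)
        risk = np.where(np.nan_to_num(high_case_frac - overall) > 0, s, 0.0)
        prot = np.where(np.nan_to_num(high_case_frac - overall) < 0, s, 0.0)
    np.fill_diagonal(risk, 0.0)
    np.fill_diagonal(prot, 0.0)
    return risk, prot


def score_pairs(dataset: GenotypeDataset, model: str) -> PairScoreMatrix:
    """Score all unordered SNP pairs under a disease model."""
    if model not in DISEASE_MODELS:
        raise ValueError(f"unknown disease model {model!r}")
    if model == "additive":
        risk, prot = _additive_scores(dataset)
    elif model in ("recessive", "dominant"):
        risk, prot = _coding_pair_scores(dataset, model, model)
    else:  # combined: max over RR, RD, DR, DD
        rr_r, rr_p = _coding_pair_scores(dataset, "recessive", "recessive")
        dd_r, dd_p = _coding_pair_scores(dataset, "dominant", "dominant")
        rd_r, rd_p = _coding_pair_scores(dataset, "recessive", "dominant")
        risk = np.maximum.reduce([rr_r, dd_r, rd_r, rd_r.T])
        prot = np.maximum.reduce([rr_p, dd_p, rd_p, rd_p.T])
    risk = np.maximum(risk, risk.T)
    prot = np.maximum(prot, prot.T)
    return PairScoreMatrix(dataset.snp_ids, risk, prot, model)


@dataclass
class InteractionNetwork:
    """Risk/protective binary adjacency at a lenient density threshold."""

    snp_ids: List[str]
    risk_adj: np.ndarray
    protective_adj: np.ndarray
    delta: float
    model: str
    rho_risk: float
    rho_protective: float

    def adjacency(self, side: str) -> np.ndarray:
        if side == "risk":
            return self.risk_adj
        if side == "protective":
            return self.protective_adj
        raise ValueError(f"side must be risk or protective, got {side!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for side in ("risk", "protective"):
            a, b = np.nonzero(np.triu(self.adjacency(side), k=1))
            for i, j in zip(a, b):
                rows.append((self.snp_ids[i], self.snp_ids[j], side))
        return pd.DataFrame(rows, columns=["snp_i", "snp_j", "side"])


def _threshold_side(scores: np.ndarray, snp_ids: Sequence[str], n_keep: int
                    ) -> np.ndarray:
    m = scores.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    s = scores[iu, ju]
    pos = s > 0
    iu, ju, s = iu[pos], ju[pos], s[pos]
    if len(s) > n_keep:
        ids = np.asarray(snp_ids)
        order = np.lexsort((ids[ju], ids[iu], -s))
        iu, ju = iu[order[:n_keep]], ju[order[:n_keep]]
    adj = np.zeros((m, m), dtype=bool)
    adj[iu, ju] = True
    return adj | adj.T


def build_interaction_network(
    dataset: GenotypeDataset,
    model: str,
    delta: float,
    scores: Optional[PairScoreMatrix] = None,
) -> InteractionNetwork:
    """Keep the top floor(delta * n_pairs) positive-scoring pairs per side.

    Ties at the cutoff break lexicographically on (snp_id_i, snp_id_j).
    If fewer positive pairs exist than the target count, all are kept and
    the realized density falls short of delta (logged).
    """
    if not (0.0 < delta <= 0.5):
        raise ValueError("delta must be in (0, 0.5]")
    if scores is None:
        scores = score_pairs(dataset, model)
    m = len(scores.snp_ids)
    tot = m * (m - 1) // 2
    n_keep = int(np.floor(delta * tot))
    risk_adj = _threshold_side(scores.risk, scores.snp_ids, n_keep)
    prot_adj = _threshold_side(scores.protective, scores.snp_ids, n_keep)
    rho_r = np.triu(risk_adj, 1).sum() / tot
    rho_p = np.triu(prot_adj, 1).sum() / tot
    for side, rho in (("risk", rho_r), ("protective", rho_p)):
        if rho < delta - 1.0 / tot:
            logger.info(
                "%s network density %.4f falls short of requested %.4f "
                "(not enough positive-scoring pairs)", side, rho, delta,
            )
    return InteractionNetwork(
        scores.snp_ids, risk_adj, prot_adj, delta, scores.model,
        float(rho_r), float(rho_p),
    )


def snp_degree(network: InteractionNetwork, side: str) -> np.ndarray:
    """Per-SNP edge count in the chosen binary network."""
    return network.adjacency(side).sum(axis=1).astype(np.int64)
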