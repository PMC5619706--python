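"""Block statistics versus brute-force edge-counting oracles."""

import numpy as np
import pytest
from scipy import stats

import pathepi as pe
from pathepi.block_tests import (
    PermutationEngine,
    _exclusive_members,
    _marginal_density,
    _observed_bpm,
    _observed_wpm,
    density_chi2_global,
    density_chi2_local,
)
from pathepi.mapping import SNPPathwayMatrix
from pathepi.network import InteractionNetwork


def chi2_global_oracle(adj, members_a, members_b):
    """Brute-force: count every unordered pair into the 2x2 table."""
    m = adj.shape[0]
    a = set(members_a)
    b = set(members_b)
    o = t = k = 0
    tot = 0
    for i in range(m):
        for j in range(i + 1, m):
            tot += 1
            edge = bool(adj[i, j])
            k += edge
            in_block = (i in a and j in b) or (i in b and j in a)
            if in_block:
                t += 1
                o += edge
    if t == 0 or o / t <= k / tot:
        return 0.0
    table = np.array([[o, t - o], [k - o, (tot - t) - (k - o)]], float)
    exp = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / tot
    if (exp == 0).any():
        return 0.0
    return float(((table - exp) ** 2 / exp).sum())


def random_network_and_membership(seed, m=10):
    rng = np.random.default_rng(seed)
    adj = rng.random((m, m)) < 0.3
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    size_a = int(rng.integers(2, m // 2))
    size_b = int(rng.integers(2, m // 2))
    perm = rng.permutation(m)
    return adj, perm[:size_a], perm[size_a:size_a + size_b]


class TestChi2Global:
    def test_hand_computed_contingency(self):
        # table [[6,14],[4,76]]: chi2 = 8 + 16/18 + 2 + 16/72
        got = density_chi2_global(o=6, t=20, k_edges=10, tot_pairs=100)
        assert got == pytest.approx(8 + 16 / 18 + 2 + 16 / 72, abs=1e-9)

    def test_density_equal_to_global_gives_zero(self):
        assert density_chi2_global(2, 20, 10, 100) == 0.0

    def test_deficit_gives_zero(self):
        assert density_chi2_global(0, 20, 10, 100) == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="INVALID_BLOCK"):
            density_chi2_global(0, 0, 10, 100)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_networks(self, seed):
        adj, a, b = random_network_and_membership(seed, m=12)
        o, t = _observed_bpm(adj, np.sort(a), np.sort(b))
        k = int(np.triu(adj, 1).sum())
        tot = 12 * 11 // 2
        got = density_chi2_global(o, t, k, tot)
        want = chi2_global_oracle(adj, a, b)
        assert got == pytest.approx(want, abs=1e-9)


class TestChi2Local:
    def test_closed_form_example(self):
        # lam=0.1, T=20, O=6: (6-2)^2/2 + (14-18)^2/18
        got = density_chi2_local(o=6, t=20, lam=0.1)
        assert got == pytest.approx(16 / 2 + 16 / 18, abs=1e-9)

    def test_observed_at_expectation_gives_zero(self):
        assert density_chi2_local(2, 20, 0.1) == 0.0

    def test_below_marginal_gives_zero(self):
        assert density_chi2_local(1, 20, 0.1) == 0.0

    def test_degenerate_marginal_warns_and_zero(self):
        with pytest.warns(UserWarning):
            assert density_chi2_local(5, 20, 0.0) == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_marginal_density_matches_brute_force(self, seed):
        adj, a, _ = random_network_and_membership(seed, m=12)
        deg = adj.sum(1)
        a = np.sort(a)
        sa = set(a.tolist())
        o = t = 0
        for i in range(12):
            for j in range(i + 1, 12):
                if i in sa or j in sa:
                    t += 1
                    o += bool(adj[i, j])
        assert _marginal_density(adj, a, deg) == pytest.approx(
            o / t, abs=1e-12)


class TestPathRanksum:
    def test_exact_maximal_separation(self):
        deg = np.array([5, 6, 7, 1, 2, 3])
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        u, p = pe.path_ranksum_test(deg, mask)
        assert u == 9.0
        assert p == pytest.approx(1 / 20, abs=1e-12)  # 1 / C(6,3)

    def test_identical_groups_p_at_least_half(self):
        deg = np.array([4, 4, 4, 4])
        mask = np.array([1, 1, 0, 0], bool)
        _, p = pe.path_ranksum_test(deg, mask)
        assert p >= 0.5

    def test_swap_symmetry_on_exact_grid(self):
        deg = np.array([5, 6, 7, 1, 2, 3])
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        _, p_fwd = pe.path_ranksum_test(deg, mask)
        _, p_rev = pe.path_ranksum_test(deg, ~mask)
        # one-tailed exact p-values of the two orientations cover the grid
        assert p_fwd + p_rev == pytest.approx(1 + 1 / 20, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pe.path_ranksum_test(np.array([1, 2]), np.array([1, 1], bool))


def toy_network_and_spm(seed=0, m=16, n_pathways=4, size=5, density=0.25):
    rng = np.random.default_rng(seed)
    adj = np.triu(rng.random((m, m)) < density, 1)
    adj = adj | adj.T
    snp_ids = [f"rs{k:03d}" for k in range(m)]
    membership = np.zeros((m, n_pathways), bool)
    for p in range(n_pathways):
        membership[rng.choice(m, size, replace=False), p] = True
    spm = SNPPathwayMatrix(snp_ids, [f"P{p}" for p in range(n_pathways)],
                           membership, {f"P{p}": size for p in range(n_pathways)},
                           {}, {})
    net = InteractionNetwork(snp_ids, adj, adj.copy(), density, "dominant",
                             float(np.triu(adj, 1).sum() / (m * (m - 1) // 2)),
                             float(np.triu(adj, 1).sum() / (m * (m - 1) // 2)))
    return net, spm


class TestPermutationNull:
    def test_p_perm_reproducible_and_bounded(self):
        net, spm = toy_network_and_spm()
        a = pe.run_block_tests(net, spm, n_perm=200, seed=5)
        b = pe.run_block_tests(net, spm, n_perm=200, seed=5)
        assert (a["p_perm"] == b["p_perm"]).all()
        assert ((a["p_perm"] > 0) & (a["p_perm"] <= 1)).all()

    def test_zero_density_block_gets_p_one(self):
        net, spm = toy_network_and_spm()
        net.risk_adj[:] = False
        out = pe.run_block_tests(net, spm, n_perm=200, seed=1, sides=["risk"])
        bpm = out[out["kind"] == "BPM"]
        assert (bpm["p_perm"] == 1.0).all()

    def test_extreme_block_gets_add_one_bound(self):
        net, spm = toy_network_and_spm(seed=3)
        # force a fully connected block between P0 and P1 exclusive members
        a = spm.members("P0")
        b = spm.members("P1")
        net.risk_adj[np.ix_(a, b)] = True
        net.risk_adj[np.ix_(b, a)] = True
        np.fill_diagonal(net.risk_adj, False)
        out = pe.run_block_tests(net, spm, n_perm=999, seed=1, sides=["risk"],
                                 kinds=["BPM"])
        row = out[out["block_id"].str.contains("P0\\|P1")].iloc[0]
        assert row["p_perm"] == pytest.approx(1 / 1000, abs=1e-12)

    def test_monotone_in_observed_density(self):
        """For a fixed size signature, p_perm never increases with the
        observed density."""
        engine = PermutationEngine(30, 500, seed=2)
        rng = np.random.default_rng(0)
        adj = np.triu(rng.random((30, 30)) < 0.2, 1)
        adj = adj | adj.T
        null = engine.null_bpm_density(adj, 5, 6)
        from pathepi.block_tests import _p_perm
        ps = [_p_perm(null, d) for d in np.linspace(0.01, 0.9, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_null_matches_exhaustive_enumeration_tiny_network(self):
        """4-SNP network: permuted densities for a (1,1) block follow the
        exhaustive distribution over ordered SNP pairs."""
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        engine = PermutationEngine(4, 3000, seed=7)
        null = engine.null_bpm_density(adj, 1, 1)
        # exhaustive: 2 edges / 6 unordered pairs -> P(density 1) = 1/3
        assert null.mean() == pytest.approx(1 / 3, abs=0.03)

    def test_uniform_on_attainable_grid(self):
        """Randomized-PIT of the permutation p is uniform for blocks drawn
        from the same law as the null (chi-square GOF over 200 blocks)."""
        rng = np.random.default_rng(4)
        m = 40
        adj = np.triu(rng.random((m, m)) < 0.15, 1)
        adj = adj | adj.T
        engine = PermutationEngine(m, 1000, seed=9)
        null = engine.null_bpm_density(adj, 6, 6)
        us = []
        for _ in range(200):
            perm = rng.permutation(m)
            a, b = perm[:6], perm[6:12]
            obs = adj[np.ix_(a, b)].sum() / 36
            gt = (null > obs + 1e-12).sum()
            eq = (np.abs(null - obs) <= 1e-12).sum()
            us.append((gt + rng.random() * (1 + eq)) / (len(null) + 1))
        hist, _ = np.histogram(us, bins=10, range=(0, 1))
        stat = ((hist - 20.0) ** 2 / 20.0).sum()
        assert stats.chi2.sf(stat, df=9) > 0.01


class TestRelabelingInvariance:
    def test_statistics_invariant_to_snp_relabeling(self):
        net, spm = toy_network_and_spm(seed=6)
        base = pe.run_block_tests(net, spm, n_perm=300, seed=8)
        perm = np.random.default_rng(1).permutation(net.n_snps)
        net2 = InteractionNetwork(
            [net.snp_ids[i] for i in perm],
            net.risk_adj[np.ix_(perm, perm)],
            net.protective_adj[np.ix_(perm, perm)],
            net.delta, net.model, net.rho_risk, net.rho_protective,
        )
        spm2 = SNPPathwayMatrix(
            [spm.snp_ids[i] for i in perm], spm.pathway_ids,
            spm.membership[perm], spm.gene_counts, {}, {},
        )
        other = pe.run_block_tests(net2, spm2, n_perm=300, seed=8)
        cols = ["chi2_global", "chi2_local", "density", "ranksum_p"]
        a = base.set_index("block_id")[cols].sort_index()
        b = other.set_index("block_id")[cols].sort_index()
        assert np.allclose(a.fillna(-1).to_numpy(), b.fillna(-1).to_numpy())
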