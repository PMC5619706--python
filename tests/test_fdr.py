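"""Sample-permutation FDR, redundancy grouping and hypothesis accounting."""

import numpy as np
import pandas as pd
import pytest

import pathepi as pe
from pathepi.mapping import SNPPathwayMatrix


def table(rows):
    """Build a minimal BPM result table: (block_id, p_perm, chi2g, chi2l)."""
    df = pd.DataFrame(rows, columns=["block_id", "p_perm", "chi2_global",
                                     "chi2_local"])
    df["kind"] = "BPM"
    df["side"] = "risk"
    df["pathway_a"] = [b.split("|")[1] for b in df["block_id"]]
    df["pathway_b"] = [b.split("|")[2] for b in df["block_id"]]
    df["ranksum_p"] = np.nan
    df["ranksum_U"] = np.nan
    return df


class TestSamplePermutationFDR:
    def test_untouched_top_result_gets_zero(self):
        real = table([("BPM|A|B|risk", 0.001, 50.0, 10.0),
                      ("BPM|A|C|risk", 0.5, 1.0, 0.5)])
        perms = [table([("BPM|A|B|risk", 0.2, 5.0, 1.0),
                        ("BPM|A|C|risk", 0.9, 0.1, 0.0)]) for _ in range(10)]
        out = pe.sample_permutation_fdr(real, perms)
        assert out.set_index("block_id").loc["BPM|A|B|risk", "fdr"] == 0.0

    def test_ratio_quarter(self):
        """4 real results above a cutoff where the permuted mean count is
        1.0 -> FDR 0.25 at the 4th rank (the reporting-threshold case)."""
        real = table([(f"BPM|A|B{k}|risk", 0.001 * (k + 1), 50.0, 10.0)
                      for k in range(4)])
        # each run has exactly one permuted result at the 4th rank's level
        perms = [table([("BPM|A|X|risk", 0.0039, 1.0, 1.0)]
                       + [(f"BPM|A|Y{j}|risk", 0.9, 0.0, 0.0)
                          for j in range(3)])
                 for _ in range(10)]
        out = pe.sample_permutation_fdr(real, perms)
        by_rank = out.sort_values("p_perm")["fdr"].tolist()
        assert by_rank[:3] == [0.0, 0.0, 0.0]
        assert by_rank[3] == pytest.approx(0.25, abs=1e-12)

    def test_quarter_without_monotonization_distortion(self):
        """Permuted results weaker than every real one except one run."""
        real = table([(f"BPM|A|B{k}|risk", 0.001 * (k + 1), 50.0 - k, 10.0)
                      for k in range(4)])
        perms = []
        for r in range(10):
            rows = [(f"BPM|A|Z{j}|risk", 0.5, 0.1, 0.1) for j in range(4)]
            perms.append(table(rows))
        # plant exactly one permuted exceedance per run at the 4th rank
        for p in perms:
            p.loc[0, "p_perm"] = 0.0041  # below real rank-4's 0.004? no: above
        out = pe.sample_permutation_fdr(real, perms)
        # permuted 0.0041 > real 0.004 -> counts only for keys >= 0.0041
        assert out.sort_values("p_perm")["fdr"].iloc[3] == pytest.approx(
            0.0, abs=1e-12)
        perms2 = [p.copy() for p in perms]
        for p in perms2:
            p.loc[0, "p_perm"] = 0.0039  # now beats the rank-4 real result
        out2 = pe.sample_permutation_fdr(real, perms2)
        assert out2.sort_values("p_perm")["fdr"].iloc[3] == pytest.approx(
            1.0 / 4, abs=1e-12)

    def test_scale_free_in_monotone_transform(self):
        rng = np.random.default_rng(0)
        real = table([(f"BPM|A|B{k}|risk", p, c, l)
                      for k, (p, c, l) in enumerate(
                          zip(rng.random(20), rng.random(20) * 30,
                              rng.random(20) * 10))])
        perms = [table([(f"BPM|A|P{k}|risk", p, c, l)
                        for k, (p, c, l) in enumerate(
                            zip(rng.random(20), rng.random(20) * 30,
                                rng.random(20) * 10))]) for _ in range(5)]
        out1 = pe.sample_permutation_fdr(real, perms)

        def transform(df):
            df = df.copy()
            df["p_perm"] = df["p_perm"] ** 3          # monotone increasing
            df["chi2_global"] = np.sqrt(df["chi2_global"])
            df["chi2_local"] = 2 * df["chi2_local"]
            return df

        out2 = pe.sample_permutation_fdr(transform(real),
                                         [transform(p) for p in perms])
        a = out1.set_index("block_id")["fdr"]
        b = out2.set_index("block_id")["fdr"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_self_permutation_floors_fdr_at_one_per_run_count(self):
        """Adding the real table as a permutation run can only raise FDRs."""
        rng = np.random.default_rng(1)
        real = table([(f"BPM|A|B{k}|risk", p, c, 1.0)
                      for k, (p, c) in enumerate(
                          zip(rng.random(15), rng.random(15) * 30))])
        perms = [table([(f"BPM|A|P{k}|risk", p, c, 1.0)
                        for k, (p, c) in enumerate(
                            zip(rng.random(15), rng.random(15) * 30))])
                 for _ in range(4)]
        base = pe.sample_permutation_fdr(real, perms)
        plus = pe.sample_permutation_fdr(real, perms + [real.copy()])
        a = base.set_index("block_id")["fdr"].sort_index()
        b = plus.set_index("block_id")["fdr"].sort_index()
        assert (b >= a - 1e-12).all()

    def test_families_estimated_separately(self):
        real = pd.concat([
            table([("BPM|A|B|risk", 0.001, 50.0, 10.0)]),
            table([("BPM|A|C|risk", 0.001, 50.0, 10.0)]).assign(
                side="protective"),
        ])
        perms = [pd.concat([
            table([("BPM|A|B|risk", 0.0001, 60.0, 10.0)]),
            table([("BPM|A|C|risk", 0.9, 0.0, 0.0)]).assign(side="protective"),
        ]) for _ in range(10)]
        out = pe.sample_permutation_fdr(real, perms).set_index("block_id")
        assert out.loc["BPM|A|B|risk", "fdr"] == 1.0
        assert out.loc["BPM|A|C|risk", "fdr"] == 0.0


def toy_spm(overlaps):
    """Pathways as index sets over 40 SNPs; overlaps maps name -> indices."""
    snp_ids = [f"rs{k:03d}" for k in range(40)]
    names = sorted(overlaps)
    membership = np.zeros((40, len(names)), bool)
    for c, name in enumerate(names):
        membership[np.asarray(overlaps[name]), c] = True
    return SNPPathwayMatrix(snp_ids, names, membership,
                            {n: 5 for n in names}, {}, {})


class TestRedundancyFilter:
    def test_duplicate_pathway_collapsed(self):
        spm = toy_spm({"A": range(10), "A2": range(10), "B": range(20, 30)})
        disc = table([("BPM|A|B|risk", 0.001, 50.0, 10.0),
                      ("BPM|A2|B|risk", 0.002, 40.0, 9.0)])
        out, groups = pe.redundancy_filter(disc, spm, 0.25)
        assert len(out) == 1
        assert out.iloc[0]["block_id"] == "BPM|A|B|risk"
        assert groups["BPM|A|B|risk"] == groups["BPM|A2|B|risk"]

    def test_disjoint_pairs_not_collapsed(self):
        spm = toy_spm({"A": range(10), "B": range(10, 20),
                       "C": range(20, 30), "D": range(30, 40)})
        disc = table([("BPM|A|B|risk", 0.001, 50.0, 10.0),
                      ("BPM|C|D|risk", 0.002, 40.0, 9.0)])
        out, groups = pe.redundancy_filter(disc, spm, 0.25)
        assert len(out) == 2
        assert groups["BPM|A|B|risk"] != groups["BPM|C|D|risk"]

    def test_transitive_closure_chains(self):
        # A ~ B and B ~ C at Jaccard 3/7 >= 0.4, but A ~ C only 1/9
        spm = toy_spm({
            "A": [0, 1, 2, 3, 4], "B": [2, 3, 4, 5, 6], "C": [4, 5, 6, 7, 8],
            "X": range(20, 25),
        })
        disc = table([("BPM|A|X|risk", 0.001, 50.0, 10.0),
                      ("BPM|B|X|risk", 0.002, 40.0, 9.0),
                      ("BPM|C|X|risk", 0.003, 30.0, 8.0)])
        out, groups = pe.redundancy_filter(disc, spm, 0.4)
        assert len(set(groups.values())) == 1
        assert len(out) == 1
        assert out.iloc[0]["block_id"] == "BPM|A|X|risk"

    def test_swapped_pair_matching(self):
        spm = toy_spm({"A": range(10), "B": range(10, 20)})
        disc = table([("BPM|A|B|risk", 0.001, 50.0, 10.0),
                      ("BPM|B|A|risk", 0.002, 40.0, 9.0)])
        out, groups = pe.redundancy_filter(disc, spm, 0.25)
        assert len(set(groups.values())) == 1

    def test_input_order_invariance(self):
        spm = toy_spm({
            "A": [0, 1, 2, 3, 4], "B": [2, 3, 4, 5, 6], "C": [4, 5, 6, 7, 8],
            "X": range(20, 25),
        })
        rows = [("BPM|A|X|risk", 0.001, 50.0, 10.0),
                ("BPM|B|X|risk", 0.002, 40.0, 9.0),
                ("BPM|C|X|risk", 0.003, 30.0, 8.0)]
        out1, _ = pe.redundancy_filter(table(rows), spm, 0.4)
        out2, _ = pe.redundancy_filter(table(rows[::-1]), spm, 0.4)
        assert out1["block_id"].tolist() == out2["block_id"].tolist()


class TestPilotSelect:
    def test_single_candidate_returned(self, planted_cohort, planted_spm):
        ds, _ = planted_cohort
        model, delta, _ = pe.pilot_select_model(ds, planted_spm, ["dominant"],
                                                [0.05], n_perm_pilot=200,
                                                seed=0)
        assert (model, delta) == ("dominant", 0.05)

    def test_planted_dominant_recovered(self, planted_cohort, planted_spm):
        ds, _ = planted_cohort
        model, delta, pilot = pe.pilot_select_model(
            ds, planted_spm, ["combined", "dominant", "recessive"],
            [0.02, 0.05], n_perm_pilot=500, seed=0,
        )
        assert model in ("dominant", "combined")

    def test_empty_candidates_rejected(self, planted_cohort, planted_spm):
        with pytest.raises(ValueError):
            pe.pilot_select_model(planted_cohort[0], planted_spm, [], [0.05])


class TestCountBPMTests:
    def test_pathway_collection_scale(self):
        # the 833-pathway catalog: > 400k unrestricted, < 2k focal
        assert pe.count_bpm_tests(833) == 693_056
        assert pe.count_bpm_tests(833) > 400_000
        assert pe.count_bpm_tests(833, restricted_to_focal=True) == 1_664
        assert pe.count_bpm_tests(833, restricted_to_focal=True) < 2_000

    def test_tiny_case(self):
        assert pe.count_bpm_tests(3) == 6

    def test_too_few_pathways_rejected(self):
        with pytest.raises(ValueError):
            pe.count_bpm_tests(1)
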