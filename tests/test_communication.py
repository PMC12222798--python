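import numpy as np
import pandas as pd
import pytest

from tmecrosstalk.communication import (CommProfile, build_profiles, communication_network,
                                        communication_table, compare_pre_post,
                                        define_subpopulations, pairwise_score,
                                        received_communication, receptor_trend_lmm,
                                        standardize_scores)
from tmecrosstalk.synthetic import CohortConfig, generate_count_cohort


def random_profile(rng, n_send=3, n_recv=3, n_path=2):
    """Random two-cell-type profile for oracle checks."""
    subs = [f"S|{i}" for i in range(n_send)] + [f"R|{i}" for i in range(n_recv)]
    ct = pd.Series(["S"] * n_send + ["R"] * n_recv, index=subs)
    P = pd.Series(rng.dirichlet(np.ones(len(subs))), index=subs)
    x = pd.DataFrame(rng.uniform(0, 50, (len(subs), n_path)), index=subs,
                     columns=[f"k{j}" for j in range(n_path)])
    y = pd.DataFrame(rng.uniform(0, 50, (len(subs), n_path)), index=subs,
                     columns=[f"k{j}" for j in range(n_path)])
    return CommProfile("s", ct, P, x, y)


def received_brute(profile, S, R, k):
    """Independent double loop over all (sender, receiver) subpopulation pairs."""
    send = [i for i in profile.cell_type.index if profile.cell_type[i] == S]
    recv = [j for j in profile.cell_type.index if profile.cell_type[j] == R]
    num = 0.0
    den = 0.0
    for j in recv:
        cj = 0.0
        for i in send:
            cj += profile.y.loc[j, k] * profile.x.loc[i, k] * profile.P_hat[i]
        num += cj * profile.P_hat[j]
        den += profile.P_hat[j]
    return num / den


class TestSubpopulations:
    def test_three_equal_bins_on_uniform_axis(self):
        idx = [f"c{i}" for i in range(90)]
        coords = pd.DataFrame({"axis1": np.linspace(0, 1, 90)}, index=idx)
        labels = define_subpopulations(coords, pd.Series("fibro", index=idx), n_bins=3)
        assert sorted(labels.value_counts()) == [30, 30, 30]

    def test_small_cell_type_single_subpopulation(self):
        idx = [f"c{i}" for i in range(29)]
        coords = pd.DataFrame({"axis1": np.linspace(0, 1, 29)}, index=idx)
        labels = define_subpopulations(coords, pd.Series("f", index=idx), n_bins=3)
        assert labels.nunique() == 1

    def test_floor_enforced_after_merging(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(200)]
        coords = pd.DataFrame({"axis1": rng.normal(size=200),
                               "axis2": rng.normal(size=200)}, index=idx)
        labels = define_subpopulations(coords, pd.Series("f", index=idx), n_bins=3)
        assert labels.value_counts().min() >= 30

    def test_cell_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(1)
        idx = [f"c{i}" for i in range(120)]
        coords = pd.DataFrame({"axis1": rng.uniform(0, 1, 120)}, index=idx)
        ct = pd.Series("f", index=idx)
        l1 = define_subpopulations(coords, ct, n_bins=3)
        perm = rng.permutation(idx)
        l2 = define_subpopulations(coords.loc[perm], ct.loc[perm], n_bins=3)
        # same partition: co-membership matrices agree
        df = pd.DataFrame({"a": l1, "b": l2.reindex(l1.index)})
        assert (df.groupby("a")["b"].nunique() == 1).all()
        assert (df.groupby("b")["a"].nunique() == 1).all()


class TestScores:
    def test_pairwise_product(self):
        assert pairwise_score(3.0, 2.0, 0.5) == 3.0
        assert pairwise_score(3.0, 2.0, 0.0) == 0.0
        assert pairwise_score(6.0, 2.0, 0.5) == 2 * pairwise_score(3.0, 2.0, 0.5)

    def test_hand_computed_weighted_average(self):
        ct = pd.Series({"s1": "S", "s2": "S", "r1": "R", "r2": "R"})
        P = pd.Series({"s1": 0.2, "s2": 0.4, "r1": 0.3, "r2": 0.1})
        x = pd.DataFrame({"k": [10.0, 0.0, 0.0, 0.0]}, index=ct.index)
        y = pd.DataFrame({"k": [0.0, 0.0, 1.0, 2.0]}, index=ct.index)
        prof = CommProfile("t", ct, P, x, y)
        # sum x P = 2; Cbar = (2*1*.3 + 2*2*.1) / .4 = 2.5
        assert received_communication(prof, "S", "R", "k") == pytest.approx(2.5, abs=1e-12)

    def test_single_receiver_reduces_to_y_times_sender_total(self):
        rng = np.random.default_rng(2)
        prof = random_profile(rng, n_recv=1)
        send = prof.cell_type.index[prof.cell_type == "S"]
        total = float((prof.x.loc[send, "k0"] * prof.P_hat[send]).sum())
        expected = float(prof.y.loc["R|0", "k0"]) * total
        assert received_communication(prof, "S", "R", "k0") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_pair_loop(self, seed):
        rng = np.random.default_rng(seed)
        prof = random_profile(rng, n_send=int(rng.integers(1, 10)),
                              n_recv=int(rng.integers(1, 10)))
        for k in prof.x.columns:
            assert received_communication(prof, "S", "R", k) == pytest.approx(
                received_brute(prof, "S", "R", k), abs=1e-12)

    def test_additive_in_sender_subpopulations(self):
        """Merging two sender subpopulations with identical x leaves C unchanged."""
        ct = pd.Series({"s1": "S", "s2": "S", "r1": "R"})
        P = pd.Series({"s1": 0.25, "s2": 0.25, "r1": 0.5})
        x = pd.DataFrame({"k": [7.0, 7.0, 0.0]}, index=ct.index)
        y = pd.DataFrame({"k": [0.0, 0.0, 3.0]}, index=ct.index)
        split = received_communication(CommProfile("t", ct, P, x, y), "S", "R", "k")
        ct2 = pd.Series({"s": "S", "r1": "R"})
        P2 = pd.Series({"s": 0.5, "r1": 0.5})
        x2 = pd.DataFrame({"k": [7.0, 0.0]}, index=ct2.index)
        y2 = pd.DataFrame({"k": [0.0, 3.0]}, index=ct2.index)
        merged = received_communication(CommProfile("t", ct2, P2, x2, y2), "S", "R", "k")
        assert split == pytest.approx(merged, abs=1e-12)

    def test_missing_pathway_nan(self):
        rng = np.random.default_rng(3)
        prof = random_profile(rng)
        assert np.isnan(received_communication(prof, "S", "R", "nope"))


class TestProfiles:
    def test_hand_built_six_cell_sample(self, erbb_pairs):
        genes = ["NRG1", "ERBB3", "other"]
        # two samples to exercise grouping; cells 10/20/... total counts
        counts = pd.DataFrame(
            [[2, 0, 4, 0, 1, 0],
             [0, 3, 0, 2, 0, 5],
             [8, 7, 6, 8, 9, 5]],
            index=genes, columns=[f"c{i}" for i in range(6)])
        meta = pd.DataFrame({
            "sample": ["a"] * 6,
            "cell_type": ["fibroblast"] * 3 + ["cancer"] * 3,
            "subpopulation": ["f|0"] * 3 + ["c|0"] * 3,
        }, index=counts.columns)
        prof = build_profiles(counts, meta, erbb_pairs)["a"]
        tot = counts.sum(axis=0)
        nrg1_cpm = (counts.loc["NRG1"] / tot * 1e6)
        assert prof.P_hat["f|0"] == pytest.approx(0.5)
        assert prof.x.loc["f|0", "NRG1_ERBB3"] == pytest.approx(nrg1_cpm[:3].mean())
        erbb3_cpm = (counts.loc["ERBB3"] / tot * 1e6)
        assert prof.y.loc["c|0", "NRG1_ERBB3"] == pytest.approx(erbb3_cpm[3:].mean())

    def test_proportions_sum_to_one(self, small_cohort, erbb_pairs):
        profiles = build_profiles(small_cohort.counts, small_cohort.cell_meta, erbb_pairs)
        for prof in profiles.values():
            assert prof.P_hat.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_ligand_annihilates(self, erbb_pairs):
        counts = pd.DataFrame([[0, 0], [5, 5], [3, 3]],
                              index=["NRG1", "ERBB3", "bg"], columns=["c0", "c1"])
        meta = pd.DataFrame({"sample": ["a", "a"], "cell_type": ["fibroblast", "cancer"],
                             "subpopulation": ["f|0", "c|0"]}, index=["c0", "c1"])
        prof = build_profiles(counts, meta, erbb_pairs)["a"]
        assert received_communication(prof, "fibroblast", "cancer", "NRG1_ERBB3") == 0.0

    def test_absent_lr_genes_dropped(self, erbb_pairs):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["NRG1", "ERBB3"],
                              columns=["c0", "c1"])
        meta = pd.DataFrame({"sample": ["a", "a"], "cell_type": ["f", "c"],
                             "subpopulation": ["f|0", "c|0"]}, index=counts.columns)
        prof = build_profiles(counts, meta, erbb_pairs)["a"]
        assert list(prof.x.columns) == ["NRG1_ERBB3"]


class TestStandardize:
    def _table(self, cs):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(cs))],
                             "sender": "S", "receiver": "R", "pathway": "k", "C": cs})

    def test_two_point_standardization(self):
        out = standardize_scores(self._table([0.0, np.e - 1.0]))
        assert sorted(out["z"].round(6)) == [-0.707107, 0.707107]

    def test_constant_scores_flagged_zero(self):
        out = standardize_scores(self._table([2.0, 2.0, 2.0]))
        assert (out["z"] == 0.0).all() and out["constant"].all()

    def test_idempotent_moments(self):
        rng = np.random.default_rng(4)
        out = standardize_scores(self._table(rng.uniform(0, 10, 12)))
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestPrePost:
    def test_identical_tables_fold_one(self):
        rows = []
        for i, s in enumerate(["a0", "a1", "b0", "b1"]):
            rows.append((s, "S", "R", "k", 5.0))
        table = pd.DataFrame(rows, columns=["sample", "sender", "receiver", "pathway", "C"])
        tp = pd.Series({"a0": 0, "a1": 1, "b0": 0, "b1": 1})
        res = compare_pre_post(table, tp)
        assert (res["fold_change"] == 1.0).all()

    def test_shifted_ligand_detected_across_seeds(self, erbb_pairs):
        detected, fold_up = 0, 0
        n_seeds = 10
        for s in range(n_seeds):
            cfg = CohortConfig(n_patients=4, n_cells_per_sample=120, n_genes=60,
                               n_pathways=2, seed=100 + s)
            cohort = generate_count_cohort(
                cfg, lr_pairs=erbb_pairs,
                shift_spec=[{"cell_type": "fibroblast", "gene": "NRG1", "fold": 3.0}])
            profiles = build_profiles(cohort.counts, cohort.cell_meta, erbb_pairs)
            table = communication_table(profiles, pairs=["NRG1_ERBB3"])
            table = table[(table.sender == "fibroblast") & (table.receiver == "cancer")]
            tp = cohort.cell_meta.groupby("sample")["t"].first()
            res = compare_pre_post(table, tp)
            row = res.iloc[0]
            fold_up += row["fold_change"] > 1.0
            detected += row["p"] < 0.05
        assert fold_up >= 9
        assert detected >= 7

    def test_null_fold_changes_center_on_one(self, erbb_pairs):
        cfg = CohortConfig(n_patients=5, n_cells_per_sample=100, n_genes=60,
                           n_pathways=2, seed=55)
        cohort = generate_count_cohort(cfg, lr_pairs=erbb_pairs, shift_spec=[])
        profiles = build_profiles(cohort.counts, cohort.cell_meta, erbb_pairs)
        table = communication_table(profiles)
        tp = cohort.cell_meta.groupby("sample")["t"].first()
        res = compare_pre_post(table, tp)
        lf = np.log(res["fold_change"].dropna())
        assert abs(lf.mean()) < 3 * lf.std() / np.sqrt(len(lf)) + 0.05


class TestReceptorTrend:
    @staticmethod
    def _family_table(delta, n_path=4, n_tumor=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tumor in range(n_tumor):
            base = rng.normal(0, 0.2)
            for t in (0, 1):
                s = f"t{tumor}_{t}"
                for k in range(n_path):
                    val = 1.0 + base + rng.normal(0, 0.05) + delta * t
                    rows.append((s, "fibro", "cancer", f"k{k}",
                                 np.expm1(max(val, 0.0)), t))
        df = pd.DataFrame(rows, columns=["sample", "sender", "receiver",
                                         "pathway", "C", "t"])
        tp = df.groupby("sample")["t"].first()
        return df.drop(columns="t"), tp

    def test_recovers_common_shift(self):
        table, tp = self._family_table(delta=0.5, seed=1)
        res = receptor_trend_lmm(table, tp)
        assert abs(res["trend"] - 0.5) < 3 * max(res["se"], 0.05)
        assert res["test"].p_value < 0.05

    def test_one_pathway_collapses_to_endpoint_model(self):
        table, tp = self._family_table(delta=0.3, n_path=1, seed=2)
        res = receptor_trend_lmm(table, tp)
        cp = compare_pre_post(table, tp).iloc[0]
        assert res["collapsed"]
        assert res["trend"] == pytest.approx(cp["estimate"], abs=1e-6)

    def test_pathway_label_shuffle_leaves_pooled_trend(self):
        table, tp = self._family_table(delta=0.4, seed=3)
        res1 = receptor_trend_lmm(table, tp)
        rng = np.random.default_rng(0)
        relabel = dict(zip([f"k{i}" for i in range(4)],
                           rng.permutation([f"k{i}" for i in range(4)])))
        shuffled = table.assign(pathway=table["pathway"].map(relabel))
        res2 = receptor_trend_lmm(shuffled, tp)
        assert res1["trend"] == pytest.approx(res2["trend"], abs=1e-6)


class TestNetwork:
    def test_all_zero_scores_zero_weights(self):
        rows = [(s, S, R, "k", 0.0) for s in ("a", "b")
                for S in ("X", "Y") for R in ("X", "Y")]
        table = pd.DataFrame(rows, columns=["sample", "sender", "receiver", "pathway", "C"])
        G = communication_network(table)
        assert all(d["weight"] == 0.0 for _, _, d in G.edges(data=True))

    def test_sample_order_invariance(self, small_cohort, erbb_pairs):
        profiles = build_profiles(small_cohort.counts, small_cohort.cell_meta, erbb_pairs)
        table = communication_table(profiles)
        tp = small_cohort.cell_meta.groupby("sample")["t"].first()
        G1 = communication_network(table, tp)
        G2 = communication_network(table.iloc[::-1].reset_index(drop=True), tp)
        for e in G1.edges:
            assert G1.edges[e]["weight"] == pytest.approx(G2.edges[e]["weight"], abs=1e-12)

    def test_shifted_edge_has_largest_fold_into_cancer(self, small_cohort, erbb_pairs):
        profiles = build_profiles(small_cohort.counts, small_cohort.cell_meta, erbb_pairs)
        nrg1 = [p for p in erbb_pairs["pathway_id"] if p.startswith("NRG1")]
        table = communication_table(profiles, pairs=nrg1)
        tp = small_cohort.cell_meta.groupby("sample")["t"].first()
        G = communication_network(table, tp)
        into_cancer = {S: d["fold_change"] for S, R, d in G.edges(data=True) if R == "cancer"}
        assert max(into_cancer, key=into_cancer.get) == "fibroblast"
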