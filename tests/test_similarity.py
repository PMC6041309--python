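import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2, rankdata, studentized_range

import lowbiome as lb


class TestSpearman:
    def test_monotone_pairs(self):
        assert lb.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert lb.spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 1.0, 3.0, 4.0])
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert lb.spearman_rho(x, y) == pytest.approx(expected)

    def test_constant_vector_flagged_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(lb.spearman_rho([1, 1, 1], [1, 2, 3]))
        assert "undefined" in caplog.text

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lb.spearman_rho([1, 2], [3, 4])


def _paired_study(n_pairs=4, identical_site="dam_oral", missing_calf=None):
    rng = np.random.default_rng(0)
    features = [f"g{i}" for i in range(12)]
    rows, counts = [], {}
    for j in range(n_pairs):
        calf, dam = f"calf{j}", f"dam{j}"
        calf_comp = rng.integers(1, 100, size=12)
        counts[f"nb.{calf}"] = calf_comp
        rows.append({"sample_id": f"nb.{calf}", "animal_id": calf, "group": "newborn", "dam_of": pd.NA})
        for site in lb.DAM_SITES:
            if missing_calf == calf and site == "dam_feces":
                continue
            comp = calf_comp * 3 if site == identical_site else rng.integers(1, 100, size=12)
            counts[f"{site}.{dam}"] = comp
            rows.append({"sample_id": f"{site}.{dam}", "animal_id": dam, "group": site, "dam_of": calf})
    table = lb.FeatureTable(pd.DataFrame(counts, index=features), {}, "genus")
    return table, lb.SampleMetadata(pd.DataFrame(rows))


class TestPairedCorrelations:
    def test_identical_composition_gives_rho_1(self):
        table, md = _paired_study()
        pc = lb.paired_group_correlations(table, md)
        assert np.allclose(pc.rho["dam_oral"], 1.0)

    def test_incomplete_block_dropped(self):
        table, md = _paired_study(missing_calf="calf1")
        pc = lb.paired_group_correlations(table, md)
        assert "calf1" not in pc.rho.index
        assert len(pc.rho) == 3

    def test_fewer_than_two_blocks_is_error(self):
        table, md = _paired_study(n_pairs=2, missing_calf="calf0")
        with pytest.raises(ValueError, match="blocks"):
            lb.paired_group_correlations(table, md)


class TestFriedman:
    def test_perfect_agreement_closed_form(self):
        # identical orderings in all 10 blocks: chi2 = 12n/(k(k+1)) * 2 = 20
        blocked = np.tile([1.0, 2.0, 3.0], (10, 1))
        res = lb.friedman_test(blocked)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 2
        assert res.p == pytest.approx(float(chi2.sf(20.0, 2)))

    def test_fully_tied_columns_give_null_result(self):
        res = lb.friedman_test(np.ones((5, 3)))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 4))
        res = lb.friedman_test(m)
        from scipy.stats import friedmanchisquare

        sp = friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(sp.statistic)
        assert res.p == pytest.approx(sp.pvalue)

    def test_tie_correction_matches_scipy(self):
        m = np.array([[1, 1, 2], [3, 2, 2], [1, 2, 3], [2, 2, 2], [1, 3, 2.0]])
        from scipy.stats import friedmanchisquare

        sp = friedmanchisquare(*m.T)
        res = lb.friedman_test(m)
        assert res.statistic == pytest.approx(sp.statistic)

    def test_incomplete_block_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="incomplete"):
            lb.friedman_test(m)

    def test_chi2_close_to_permutation_p_in_the_tail(self):
        # strong separation at n=4, k=3: the approximation is accurate there
        m = np.tile([1.0, 2.0, 3.0], (4, 1)) + np.random.default_rng(1).normal(0, 0.05, (4, 3))
        obs = lb.friedman_test(m)
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        stats = []
        for combo in itertools.product(perms, repeat=4):
            cs = np.array(combo).sum(axis=0)
            stats.append(12 / (4 * 3 * 4) * np.sum(cs**2) - 3 * 4 * 4)
        p_exact = np.mean(np.array(stats) >= obs.statistic - 1e-9)
        assert abs(obs.p - p_exact) < 0.02


class TestNemenyi:
    def test_identical_columns_pair_has_p_1(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=6)
        blocked = np.column_stack([a, a, rng.normal(size=6)])
        p = lb.nemenyi_posthoc(blocked)
        assert p.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(p, p.T)
        assert (np.diag(p) == 1).all()

    def test_perfect_separation_n10(self):
        blocked = np.tile([1.0, 2.0, 3.0], (10, 1))
        p = lb.nemenyi_posthoc(blocked)
        # extreme pair: q = 2/sqrt(k(k+1)/(12n)) = 6.325
        q_far = 2.0 / np.sqrt(3 * 4 / (12 * 10))
        assert p.iloc[0, 2] == pytest.approx(float(studentized_range.sf(q_far, 3, np.inf)), rel=1e-6)
        assert p.iloc[0, 2] < 0.05
        # adjacent pairs sit just above 0.05 under the q approximation
        q_near = 1.0 / np.sqrt(3 * 4 / (12 * 10))
        assert p.iloc[0, 1] == pytest.approx(float(studentized_range.sf(q_near, 3, np.inf)), rel=1e-6)

    def test_p_decreases_with_more_blocks_at_fixed_rank_gap(self):
        p_small = lb.nemenyi_posthoc(np.tile([1.0, 2.0, 3.0], (5, 1))).iloc[0, 1]
        p_large = lb.nemenyi_posthoc(np.tile([1.0, 2.0, 3.0], (20, 1))).iloc[0, 1]
        assert p_large < p_small


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert lb.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert lb.bray_curtis([1, 0, 2], [0, 5, 0]) == 1.0

    def test_hand_computed_value(self):
        assert lb.bray_curtis([6, 4, 0], [2, 4, 4]) == pytest.approx(0.4)

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            lb.bray_curtis([0, 0], [0, 0])

    @given(
        x=st.lists(st.integers(0, 50), min_size=3, max_size=8),
        y=st.lists(st.integers(0, 50), min_size=3, max_size=8),
    )
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) == 0 and sum(y) == 0:
            return
        d = lb.bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(lb.bray_curtis(y, x))


class TestPCoA:
    def test_collinear_points_recover_the_line(self):
        d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        res = lb.pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(100.0)
        axis = np.sort(res.coordinates["PCo1"].to_numpy())
        assert np.diff(axis) == pytest.approx([1.0, 1.0])

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(20, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = lb.pcoa(d)
        coords = res.coordinates.to_numpy()[:, :2]
        d2 = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.abs(d2 - d).max() < 1e-9

    def test_bray_curtis_matrix_flags_negative_eigenvalues(self, study42):
        genus = lb.aggregate(study42.table, "genus")
        md = study42.metadata
        sids = (
            md.samples_in_group("newborn")
            + md.samples_in_group("dam_oral")
            + md.samples_in_group("dam_feces")
            + md.samples_in_group("dam_vestibule")
        )
        res = lb.pcoa(lb.bray_curtis_matrix(genus, sids))
        assert res.negative_eigenvalues
        assert res.coordinates.shape[0] == len(sids)
        assert res.proportion_explained.sum() == pytest.approx(100.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            lb.pcoa(np.array([[0, 1.0], [2.0, 0]]))

    def test_matches_skbio_classical_scaling(self):
        from skbio.stats.ordination import pcoa as skb_pcoa

        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ours = lb.pcoa(d)
        theirs = skb_pcoa(d, method="eigh")
        k = 3
        assert np.allclose(
            np.sort(ours.eigenvalues[:k]), np.sort(theirs.eigvals.to_numpy()[:k]), atol=1e-8
        )
        for i in range(k):
            a = ours.coordinates.to_numpy()[:, i]
            b = theirs.samples.to_numpy()[:, i]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


class TestVenn:
    def _study(self, comps):
        features = [f"g{i}" for i in range(4)]
        counts, rows = {}, []
        for g, samples in comps.items():
            for i, comp in enumerate(samples):
                sid = f"{g}.{i}"
                counts[sid] = comp
                rows.append({"sample_id": sid, "animal_id": sid, "group": g})
        table = lb.FeatureTable(pd.DataFrame(counts, index=features), {}, "genus")
        return table, lb.SampleMetadata(pd.DataFrame(rows))

    def test_identical_groups_all_shared(self):
        comp = [[5, 5, 5, 0]] * 3
        table, md = self._study({"newborn": comp, "dam_oral": comp})
        part = lb.shared_taxa_partition(table, md, ["newborn", "dam_oral"])
        assert part.region_counts[("newborn", "dam_oral")] == 3
        assert part.region_counts[("newborn",)] == 0
        assert part.universe == 3

    def test_disjoint_groups(self):
        table, md = self._study(
            {"newborn": [[5, 5, 0, 0]] * 3, "dam_oral": [[0, 0, 5, 5]] * 3}
        )
        part = lb.shared_taxa_partition(table, md, ["newborn", "dam_oral"])
        assert part.region_counts[("newborn",)] == 2
        assert part.region_counts[("dam_oral",)] == 2
        assert part.region_counts[("newborn", "dam_oral")] == 0

    def test_presence_is_majority_detection(self):
        # taxon g0 present in 1 of 3 samples: median 0, not "present"
        table, md = self._study({"newborn": [[9, 1, 0, 0], [0, 1, 0, 0], [0, 1, 0, 0]],
                                 "dam_oral": [[1, 1, 0, 0]] * 3})
        part = lb.shared_taxa_partition(table, md, ["newborn", "dam_oral"])
        assert "g0" not in part.presence["newborn"]
        assert "g0" in part.presence["dam_oral"]

    def test_three_group_regions_match_set_algebra(self):
        rng = np.random.default_rng(21)
        comps = {
            g: [list(rng.integers(0, 3, size=4) * 5) for _ in range(3)]
            for g in ("newborn", "dam_oral", "dam_feces")
        }
        table, md = self._study(comps)
        part = lb.shared_taxa_partition(table, md, list(comps))
        sets = part.presence
        for combo, count in part.region_counts.items():
            expected = set.intersection(*[set(sets[g]) for g in combo])
            for other in comps:
                if other not in combo:
                    expected -= set(sets[other])
            assert count == len(expected)
        assert sum(part.region_counts.values()) == part.universe


class TestCoexistence:
    def _study(self):
        features = ["gA", "gB", "gC"]
        counts, rows = {}, []
        calf_counts = {"calf0": [50, 19, 30], "calf1": [50, 19, 0], "calf2": [50, 19, 30]}
        dam_counts = {
            "dam0": {"dam_oral": [100, 100, 100], "dam_feces": [0, 100, 100], "dam_vestibule": [100, 100, 0]},
            "dam1": {"dam_oral": [100, 100, 100], "dam_feces": [100, 100, 0], "dam_vestibule": [0, 100, 0]},
            "dam2": {"dam_oral": [100, 100, 100], "dam_feces": [0, 100, 19], "dam_vestibule": [100, 100, 0]},
        }
        for j, (calf, v) in enumerate(calf_counts.items()):
            counts[f"nb.{calf}"] = v
            rows.append({"sample_id": f"nb.{calf}", "animal_id": calf, "group": "newborn", "dam_of": pd.NA})
            for site, w in dam_counts[f"dam{j}"].items():
                counts[f"{site}.dam{j}"] = w
                rows.append({"sample_id": f"{site}.dam{j}", "animal_id": f"dam{j}", "group": site, "dam_of": calf})
        table = lb.FeatureTable(pd.DataFrame(counts, index=features), {}, "genus")
        return table, lb.SampleMetadata(pd.DataFrame(rows))

    def test_19_read_taxon_excluded_by_cutoff(self):
        table, md = self._study()
        res = lb.coexistence_matrix(table, md)
        assert "gB" not in res.matrix.index  # 19 reads everywhere < 20

    def test_saturated_taxon_scores_1_in_oral(self):
        table, md = self._study()
        res = lb.coexistence_matrix(table, md)
        assert res.matrix.loc["gA", "dam_oral"] == pytest.approx(1.0)

    def test_conditional_counting_matches_brute_force(self):
        table, md = self._study()
        res = lb.coexistence_matrix(table, md)
        # gC: present (>=20) in calves 0 and 2 only; dam feces >=20 for dam0
        # but not dam2 (19 reads) -> 1/2
        assert res.matrix.loc["gC", "dam_feces"] == pytest.approx(0.5)
        assert res.matrix.loc["gC", "dam_vestibule"] == pytest.approx(0.0)
        assert res.calf_occurrence["gC"] == pytest.approx(2 / 3)

    def test_no_qualifying_taxa_yields_empty_matrix(self, caplog):
        table, md = self._study()
        with caplog.at_level("WARNING"):
            res = lb.coexistence_matrix(table, md, hit_cutoff=10**6)
        assert res.matrix.empty
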