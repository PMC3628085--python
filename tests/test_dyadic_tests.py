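import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import famshare as fs
from .conftest import euclidean_dm
from .oracles import naive_permanova_f


def metadata_from(rows):
    return fs.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def couple_rows(n_families, site="forehead", extra=()):
    rows = []
    for f in range(n_families):
        fam = f"F{f:02d}"
        for role, tag in (("adult_M", "M"), ("adult_F", "F")):
            rows.append({"sample_id": f"{fam}.{tag}.{site}",
                         "host_id": f"{fam}.{tag}", "family_id": fam,
                         "body_site": site, "species": "human", "role": role,
                         "age": 35.0, "has_dog": False, "has_cat": False,
                         "family_size": 2})
    rows.extend(extra)
    return rows


class TestBuildDyads:
    def test_spouses_pair_enumeration(self):
        md = metadata_from(couple_rows(3))
        pairs = fs.build_dyads(md, "spouses", "forehead")
        assert len(pairs.within) == 3
        assert len(pairs.between) == 6  # 3x3 male-female combos minus couples
        md2 = metadata_from(couple_rows(2))
        p2 = fs.build_dyads(md2, "spouses", "forehead")
        assert (len(p2.within), len(p2.between)) == (2, 2)

    def test_families_combinatorics(self):
        # family of 3 + family of 2 -> C(3,2) + C(2,2) = 4 within pairs
        rows = couple_rows(2)
        rows.append({"sample_id": "F00.K1.forehead", "host_id": "F00.K1",
                     "family_id": "F00", "body_site": "forehead",
                     "species": "human", "role": "child", "age": 8.0,
                     "has_dog": False, "has_cat": False, "family_size": 3})
        md = metadata_from(rows)
        pairs = fs.build_dyads(md, "families", "forehead")
        assert len(pairs.within) == 4
        assert len(pairs.between) == 6  # 3 x 2 cross-household pairs

    def test_child_age_window(self):
        rows = couple_rows(2)
        for fam, age in (("F00", 2.0), ("F01", 10.0)):
            rows.append({"sample_id": f"{fam}.K1.forehead",
                         "host_id": f"{fam}.K1", "family_id": fam,
                         "body_site": "forehead", "species": "human",
                         "role": "child", "age": age, "has_dog": False,
                         "has_cat": False, "family_size": 3})
        md = metadata_from(rows)
        pairs = fs.build_dyads(md, "father_child", "forehead")
        # only the 10-year-old is in the 3-18 window
        assert {b for _, b in pairs.within + pairs.between} == {"F01.K1.forehead"}

    def test_missing_infants_is_error(self):
        md = metadata_from(couple_rows(3))
        with pytest.raises(ValueError):
            fs.build_dyads(md, "father_infant", "forehead")

    def test_single_family_is_error(self):
        md = metadata_from(couple_rows(1))
        with pytest.raises(ValueError, match="fewer than 2"):
            fs.build_dyads(md, "spouses", "forehead")

    def test_owner_dog_pairs_split_by_household(self):
        rows = []
        for f, has_dog in ((0, True), (1, True), (2, False)):
            fam = f"F{f:02d}"
            rows.append({"sample_id": f"{fam}.M.forehead", "host_id": f"{fam}.M",
                         "family_id": fam, "body_site": "forehead",
                         "species": "human", "role": "adult_M", "age": 40.0,
                         "has_dog": has_dog, "has_cat": False, "family_size": 2})
            if has_dog:
                rows.append({"sample_id": f"{fam}.D1.forehead",
                             "host_id": f"{fam}.D1", "family_id": fam,
                             "body_site": "forehead", "species": "dog",
                             "role": "dog", "age": 4.0, "has_dog": True,
                             "has_cat": False, "family_size": 2})
        md = metadata_from(rows)
        own = fs.build_dyads(md, "owner_own_dog", "forehead")
        assert len(own.within) == 2   # each owner with their own dog
        assert len(own.between) == 2  # each owner with the other family's dog
        non = fs.build_dyads(md, "nonowner_dog", "forehead")
        assert len(non.within) == 0 and len(non.between) == 2


class TestAnosimR:
    def test_worked_examples(self):
        assert fs.anosim_r([0.1, 0.2], [0.3, 0.4]) == pytest.approx(1.0)
        assert fs.anosim_r([0.1, 0.3], [0.2, 0.4]) == pytest.approx(0.5)
        assert fs.anosim_r([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(0.0)

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.random(rng.integers(1, 8))
            b = rng.random(rng.integers(1, 8))
            r = fs.anosim_r(w, b)
            assert -1.0 <= r <= 1.0
            assert fs.anosim_r(b, w) == pytest.approx(-r)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            fs.anosim_r([], [0.1])


class TestDyadPermutationTest:
    def test_perfect_separation(self, couples_metadata):
        # couples coincide; different households are far apart
        pts = []
        for f in range(12):
            center = [10.0 * f, 0.0]
            pts.extend([center, center])
        dm = euclidean_dm(pts, couples_metadata.sample_ids)
        res = fs.dyad_permutation_test(dm, couples_metadata, "spouses",
                                       "forehead", n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.01
        assert res.mean_within < res.mean_between

    def test_every_between_exceeds_within_when_r_is_one(self, couples_metadata):
        pts = [[f, 0.05 * (i % 2)] for f in range(12) for i in range(2)]
        dm = euclidean_dm(pts, couples_metadata.sample_ids)
        res = fs.dyad_permutation_test(dm, couples_metadata, "spouses",
                                       "forehead", n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_deterministic_p(self, couples_metadata):
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.normal(size=(24, 3)), couples_metadata.sample_ids)
        a = fs.dyad_permutation_test(dm, couples_metadata, "spouses",
                                     "forehead", n_perm=500, seed=7)
        b = fs.dyad_permutation_test(dm, couples_metadata, "spouses",
                                     "forehead", n_perm=500, seed=7)
        assert a.p_value == b.p_value and a.r == b.r

    def test_p_floor(self, couples_metadata):
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.normal(size=(24, 3)), couples_metadata.sample_ids)
        res = fs.dyad_permutation_test(dm, couples_metadata, "spouses",
                                       "forehead", n_perm=99, seed=0)
        assert res.p_value >= 1.0 / 100.0

    def test_few_permutations_warns(self):
        md = metadata_from(couple_rows(2))
        dm = euclidean_dm(np.arange(8).reshape(4, 2), md.sample_ids)
        with pytest.warns(UserWarning, match="distinct permutations"):
            res = fs.dyad_permutation_test(dm, md, "spouses", "forehead",
                                           n_perm=99, seed=0)
        assert res.warning is not None

    def test_calibration_under_null_quick(self, couples_metadata):
        """p-values are ~uniform for iid samples (400 datasets)."""
        rng = np.random.default_rng(12345)
        ps = []
        for k in range(400):
            dm = euclidean_dm(rng.normal(size=(24, 4)),
                              couples_metadata.sample_ids)
            ps.append(fs.dyad_permutation_test(
                dm, couples_metadata, "spouses", "forehead",
                n_perm=99, seed=k).p_value)
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert 0.02 <= rate <= 0.08


class TestPermanova:
    def hand_matrix(self):
        d = np.array([[0.0, 0.1, 1.0, 1.0],
                      [0.1, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.1],
                      [1.0, 1.0, 0.1, 0.0]])
        return DistanceMatrix(d, list("abcd"))

    def test_hand_computation(self):
        res = fs.permanova_oneway(self.hand_matrix(), ["g1", "g1", "g2", "g2"],
                                  seed=0)
        assert res.pseudo_f == pytest.approx(199.0)
        assert (res.df_between, res.df_residual) == (1, 2)
        assert res.p_value <= 0.5  # only 3 distinct splits of 4 samples

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            groups = rng.choice(["a", "b", "c"], size=n)
            if len(set(groups)) < 2 or n - len(set(groups)) < 1:
                continue
            dm = DistanceMatrix(d, [f"s{i}" for i in range(n)])
            res = fs.permanova_oneway(dm, groups, n_perm=9, seed=0)
            assert res.pseudo_f == pytest.approx(
                naive_permanova_f(d, groups), abs=1e-9)

    def test_matches_scikit_bio_statistic(self):
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(10)])
        groups = ["a"] * 5 + ["b"] * 5
        ours = fs.permanova_oneway(dm, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_all_equal_distances_gives_f_one(self):
        # mutually equidistant points: between and within mean squares match
        d = 0.7 * (1 - np.eye(6))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(6)])
        res = fs.permanova_oneway(dm, ["a", "a", "b", "b", "c", "c"], seed=0)
        assert res.pseudo_f == pytest.approx(1.0)

    def test_zero_within_flagged_infinite(self):
        d = np.array([[0.0, 0.0, 1.0, 1.0],
                      [0.0, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.0],
                      [1.0, 1.0, 0.0, 0.0]])
        dm = DistanceMatrix(d, list("abcd"))
        res = fs.permanova_oneway(dm, ["g1", "g1", "g2", "g2"], seed=0)
        assert math.isinf(res.pseudo_f)
        assert 0 < res.p_value <= 1

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(77)
        ps = []
        for k in range(200):
            pts = rng.normal(size=(12, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"s{i}" for i in range(12)])
            groups = ["a"] * 6 + ["b"] * 6
            ps.append(fs.permanova_oneway(dm, groups, n_perm=99, seed=k).p_value)
        assert 0.02 <= np.mean(np.asarray(ps) <= 0.05) <= 0.09
        assert abs(np.mean(ps) - 0.5) < 0.06


class TestAgeTrajectory:
    def ages_metadata(self, ages, site="fecal"):
        rows = []
        for i, age in enumerate(ages):
            fam = f"F{i:02d}"  # everyone in their own household
            role = ("infant" if age < 1 else "child" if age < 18
                    else "adult_M" if age < 60 else "senior")
            rows.append({"sample_id": f"{fam}.P.{site}", "host_id": f"{fam}.P",
                         "family_id": fam, "body_site": site,
                         "species": "human", "role": role, "age": age,
                         "has_dog": False, "has_cat": False, "family_size": 1})
        return metadata_from(rows)

    def test_constant_distances_flat_fit(self):
        ages = [0.5, 5, 20, 35, 40, 44, 70]
        md = self.ages_metadata(ages)
        n = len(ages)
        d = 0.5 * (1 - np.eye(n))
        dm = DistanceMatrix(d, md.sample_ids)
        res = fs.age_trajectory(dm, md, "fecal")
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_age_signal_recovered_from_generator(self):
        """Young children sit far from the adult gut baseline and converge.

        Weighted UniFrac is the sensitive probe because the infant
        signature is an abundance shift; the family effect is switched
        off so the age gradient is measured in isolation.
        """
        slopes, r2s = [], []
        for seed in range(3):
            cfg = fs.SimulationConfig(
                n_families_by_type=(20, 0, 0, 2), n_taxa=100,
                depth_meanlog=math.log(5000), depth_sdlog=0.0,
                kappa_family=math.inf, w_sp=0.0, w_dog=0.0, seed=seed)
            table, tree, md = fs.simulate_dataset(cfg)
            sids = list(md.frame[(md.frame["body_site"] == "fecal")
                                 & (md.frame["species"] == "human")].index)
            dm = fs.weighted_unifrac_matrix(table.select_samples(sids), tree)
            res = fs.age_trajectory(dm, md, "fecal",
                                    target_ages=lambda a: a < 6.0)
            slopes.append(res.slope)
            r2s.append(res.r_squared)
        assert all(s < 0 for s in slopes)
        assert np.median(r2s) > 0.5

    def test_minimal_baseline_of_two(self):
        ages = [1.0, 35.0, 40.0, 10.0]
        md = self.ages_metadata(ages)
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(4, 2)), md.sample_ids)
        res = fs.age_trajectory(dm, md, "fecal")
        assert (res.per_participant["n_baseline"] <= 2).all()

    def test_too_few_baseline_adults_is_error(self):
        md = self.ages_metadata([1.0, 5.0, 35.0])
        dm = euclidean_dm(np.arange(6).reshape(3, 2), md.sample_ids)
        with pytest.raises(ValueError, match="baseline"):
            fs.age_trajectory(dm, md, "fecal")


class TestMinDetectableEffect:
    def test_study_sized_inputs(self):
        assert fs.min_detectable_effect(2757, 3071, 0.05, 0.90) == \
            pytest.approx(0.085, abs=5e-4)

    def test_symmetry(self):
        assert fs.min_detectable_effect(50, 80) == \
            pytest.approx(fs.min_detectable_effect(80, 50))

    def test_closed_form_example(self):
        assert fs.min_detectable_effect(100, 100, 0.05, 0.80) == \
            pytest.approx(0.396, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fs.min_detectable_effect(1, 10)
        with pytest.raises(ValueError):
            fs.min_detectable_effect(10, 10, alpha=1.5)
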