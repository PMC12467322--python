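"""Bray-Curtis, PERMANOVA, NMDS, and diet profiles."""

import numpy as np
import pandas as pd
import pytest

from beenet import (
    bray_curtis,
    build_block_networks,
    diet_profiles,
    dissimilarity_matrix,
    nmds,
    permanova,
    profiles_to_matrix,
)
from beenet.nicheshift import DegenerateDesignError


def bray_oracle(p, q):
    """Element-by-element textbook formula, no library calls."""
    num = 2 * sum(min(a, b) for a, b in zip(p, q))
    den = sum(p) + sum(q)
    return 1 - num / den


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 1, 0], [0, 0, 2], 1.0),
            ([1, 1, 0], [0, 1, 1], 0.5),
        ],
    )
    def test_anchors(self, p, q, expected):
        assert bray_curtis(np.array(p), np.array(q)) == pytest.approx(expected)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(12) * (rng.random(12) < 0.7)
            q = rng.random(12) * (rng.random(12) < 0.7)
            if p.sum() == 0 and q.sum() == 0:
                continue
            assert bray_curtis(p, q) == pytest.approx(
                bray_oracle(p, q), abs=1e-12
            )

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([-1.0, 1.0]), np.array([1.0, 1.0]))


def null_distance_matrix(rng, n=12, p=6):
    X = rng.lognormal(0, 1, (n, p))
    return dissimilarity_matrix(pd.DataFrame(X))


class TestPermanova:
    def test_matches_scikit_bio(self):
        """Pseudo-F agrees with the independent reference implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(4)
        D = null_distance_matrix(rng)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(D, groups, n_permutations=999, seed=0)
        ref = skbio_permanova(
            DistanceMatrix(D.to_numpy()), grouping=groups, permutations=999
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)
        assert abs(ours.p_value - ref["p-value"]) < 0.05

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(8)
        D = null_distance_matrix(rng)
        groups = ["a"] * 6 + ["b"] * 6
        r1 = permanova(D, groups, seed=123)
        r2 = permanova(D, groups, seed=123)
        assert (r1.pseudo_f, r1.p_value) == (r2.pseudo_f, r2.p_value)

    def test_complete_separation_gives_extreme_p(self):
        """Disjoint-support groups: observed F is maximal, p is near the
        1/1000 floor (ties occur only when a permutation recreates the
        original split)."""
        profiles = np.zeros((10, 6))
        profiles[:5, :3] = np.random.default_rng(1).random((5, 3)) + 0.5
        profiles[5:, 3:] = np.random.default_rng(2).random((5, 3)) + 0.5
        D = dissimilarity_matrix(pd.DataFrame(profiles))
        res = permanova(D, ["a"] * 5 + ["b"] * 5, n_permutations=999, seed=3)
        assert res.p_value >= 1 / 1000
        assert res.p_value <= 0.03
        assert res.r_squared > 0.8

    def test_duplicating_samples_preserves_r_squared(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.lognormal(0, 1, (8, 5)))
        groups = ["a"] * 4 + ["b"] * 4
        base = permanova(dissimilarity_matrix(X), groups, seed=0)
        doubled = permanova(
            dissimilarity_matrix(pd.concat([X, X], ignore_index=True)),
            groups * 2,
            seed=0,
        )
        assert np.isfinite(doubled.pseudo_f)
        assert doubled.r_squared == pytest.approx(base.r_squared, abs=1e-10)

    def test_single_member_group_rejected(self):
        rng = np.random.default_rng(10)
        D = null_distance_matrix(rng, n=5)
        with pytest.raises(DegenerateDesignError):
            permanova(D, ["a", "a", "a", "a", "b"])

    def test_null_p_values_roughly_uniform(self):
        """Exchangeable data: p-values spread over (0,1] without clumping."""
        rng = np.random.default_rng(11)
        pvals = [
            permanova(
                null_distance_matrix(rng),
                ["a"] * 6 + ["b"] * 6,
                n_permutations=199,
                seed=int(rng.integers(2**31 - 1)),
            ).p_value
            for _ in range(300)
        ]
        from scipy.stats import kstest

        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.08


class TestNmds:
    def test_planar_distances_embed_with_negligible_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 2], [2, 1], [0.5, 1.5]])
        from scipy.spatial.distance import pdist, squareform

        D = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(D, k=2, n_restarts=8, seed=0)
        assert res.stress < 1e-3
        np.testing.assert_allclose(
            res.coordinates.mean(axis=0).to_numpy(), 0.0, atol=1e-9
        )

    def test_stress_is_rank_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.random((7, 4))
        D = dissimilarity_matrix(pd.DataFrame(X))
        base = nmds(D, n_restarts=8, seed=1).stress
        transformed = nmds(np.sqrt(D), n_restarts=8, seed=1).stress
        assert abs(base - transformed) < 1e-3

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, (5, 4)) + [1, 1, 0, 0]
        b = rng.normal(0, 0.05, (5, 4)) + [0, 0, 1, 1]
        D = dissimilarity_matrix(pd.DataFrame(np.abs(np.vstack([a, b]))))
        res = nmds(D, n_restarts=10, seed=2)
        coords = res.coordinates.to_numpy()
        within = max(
            np.linalg.norm(coords[i] - coords[j])
            for g in (range(5), range(5, 10))
            for i in g
            for j in g
        )
        between = min(
            np.linalg.norm(coords[i] - coords[j])
            for i in range(5)
            for j in range(5, 10)
        )
        assert between > within

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(pd.DataFrame(np.zeros((2, 2))), k=2)


class TestDietProfiles:
    def _block_records(self):
        rows = []
        for r, plant, grains in [(1, "L1", 6), (2, "L2", 6), (3, "L1", 6), (4, "L1", 6)]:
            rows.append(
                {
                    "individual_id": f"i{r}",
                    "bee_species": "B1",
                    "plot_id": "P1",
                    "plot_type": "nearby",
                    "survey_round": r,
                    "plant_species": plant,
                    "grain_count": grains,
                }
            )
        return pd.DataFrame(rows)

    def test_proportions_sum_to_one(self, community):
        nets = []
        for _, sub in community.pollen_records.groupby("plot_id"):
            nets.extend(build_block_networks(sub, block_size=2))
        species = sorted({sp for n in nets for sp in n.bee_species})[:4]
        profiles = diet_profiles(nets, species, combine_adjacent=True)
        sums = profiles.groupby(["bee_species", "sample_id"])["proportion"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_adjacent_blocks_merge_additively(self):
        nets = build_block_networks(self._block_records(), block_size=1)
        profiles = diet_profiles(nets, {"B1"}, combine_adjacent=True)
        merged = profiles_to_matrix(profiles, "B1")
        # rounds (1,2) merge: (1 L1) + (1 L2) -> (0.5, 0.5)
        first = merged.loc["P1:b0"]
        assert first["L1"] == pytest.approx(0.5)
        assert first["L2"] == pytest.approx(0.5)
        # rounds (3,4): L1 only
        assert merged.loc["P1:b1", "L1"] == pytest.approx(1.0)

    def test_season_block_proportions(self):
        nets = build_block_networks(self._block_records(), block_size=4)
        profiles = diet_profiles(nets, {"B1"}, combine_adjacent=False)
        row = profiles_to_matrix(profiles, "B1").iloc[0]
        assert row["L1"] == pytest.approx(0.75)
        assert row.sum() == pytest.approx(1.0)

    def test_single_plant_specialist_is_unit_vector(self):
        records = self._block_records().assign(plant_species="L1")
        records = records.drop_duplicates(["individual_id", "plant_species"])
        nets = build_block_networks(records, block_size=4)
        profiles = diet_profiles(nets, {"B1"}, combine_adjacent=False)
        row = profiles_to_matrix(profiles, "B1").iloc[0]
        assert row.tolist() == [1.0]

    def test_unknown_species_rejected(self):
        nets = build_block_networks(self._block_records(), block_size=2)
        with pytest.raises(ValueError, match="absent"):
            diet_profiles(nets, {"NoSuchBee"})
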