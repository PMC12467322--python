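"""Müller's index, abundance adjustment, and pairwise PAC."""

import numpy as np
import pandas as pd
import pytest

from beenet import (
    HONEYBEE,
    HoneybeeProfile,
    UndefinedIndexError,
    adjust_matrix,
    build_network,
    honeybee_profile,
    muller_index,
    muller_matrix,
    pac_table,
    pairwise_pac,
)
from beenet.network import InteractionMatrix

from conftest import make_records


def random_adjusted(rng, n_rows=10, n_cols=20):
    """Random positive-rowsum matrix playing the role of adjusted strengths."""
    m = rng.random((n_rows, n_cols)) * (rng.random((n_rows, n_cols)) < 0.4)
    m[m.sum(axis=1) == 0, 0] = 0.5  # ensure positive row sums
    return pd.DataFrame(
        m,
        index=[f"B{i}" for i in range(n_rows)],
        columns=[f"L{j}" for j in range(n_cols)],
    )


def muller_loop_oracle(values: pd.DataFrame, i: str, j: str) -> float:
    """Naive per-term summation of the index, kept free of vectorization."""
    a = values.to_numpy(float)
    ri, rj = list(values.index).index(i), list(values.index).index(j)
    total = 0.0
    for k in range(a.shape[1]):
        if a[ri, k] == 0:
            continue
        row_share = a[ri, k] / sum(a[ri, :])
        col_share = a[rj, k] / sum(a[:, k])
        total += row_share * col_share
    return total


class TestAdjustMatrix:
    def _net(self, counts, specimens):
        counts = pd.DataFrame(counts)
        return InteractionMatrix(
            "N1", "nearby", counts, pd.Series(specimens, index=counts.index)
        )

    def test_row_divided_by_specimens(self):
        net = self._net({"P1": {"B1": 4}, "P2": {"B1": 2}}, {"B1": 4})
        adj = adjust_matrix(net)
        assert adj.values.loc["B1"].tolist() == [1.0, 0.5]

    def test_invariant_to_joint_scaling(self):
        base = self._net({"P1": {"B1": 4}, "P2": {"B1": 2}}, {"B1": 4})
        scaled = self._net({"P1": {"B1": 12}, "P2": {"B1": 6}}, {"B1": 12})
        pd.testing.assert_frame_equal(
            adjust_matrix(base).values, adjust_matrix(scaled).values
        )

    def test_zero_specimens_named_in_error(self):
        net = self._net({"P1": {"B1": 0}}, {"B1": 0})
        net.counts.loc["B1", "P1"] = 0
        with pytest.raises(UndefinedIndexError, match="B1"):
            adjust_matrix(net)

    def test_honeybee_mean_specimens_divisor(self):
        """Honeybee row uses the cross-plot mean specimen count."""
        nets = []
        for plot, spec, p1 in zip(("N1", "N2", "N3"), (10, 20, 30), (10, 15, 15)):
            counts = pd.DataFrame({"P1": {HONEYBEE: p1}, "P2": {HONEYBEE: 0}})
            nets.append(
                InteractionMatrix(
                    plot, "nearby", counts, pd.Series({HONEYBEE: spec})
                )
            )
        # pooled row (10+15+15, 0) = (40, 0); a_hb = mean(10, 20, 30) = 20
        hb = honeybee_profile(nets)
        assert hb.a_hb == 20.0
        assert hb.adjusted["P1"] == pytest.approx(2.0)
        assert hb.adjusted["P2"] == 0.0


class TestMullerIndex:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            values = random_adjusted(rng)
            d = muller_matrix(values)
            np.testing.assert_allclose(
                d.sum(axis=1).to_numpy(), 1.0, atol=1e-12, rtol=0
            )

    def test_disjoint_rows_share_nothing(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 1.0]],
            index=["B1", "B2"],
            columns=list("wxyz"),
        )
        assert muller_index(values, "B1", "B2") == 0.0

    def test_hand_summed_two_row_example(self):
        # a = [[2,1,0],[1,1,2]]: d_12 = (2/3)(1/3) + (1/3)(1/2) + 0 = 7/18
        values = pd.DataFrame(
            [[2.0, 1.0, 0.0], [1.0, 1.0, 2.0]], index=["B1", "B2"], columns=list("xyz")
        )
        assert muller_index(values, "B1", "B2") == pytest.approx(7 / 18, abs=1e-15)

    def test_zero_row_is_undefined(self):
        values = pd.DataFrame(
            [[0.0, 0.0], [1.0, 1.0]], index=["B1", "B2"], columns=list("xy")
        )
        with pytest.raises(UndefinedIndexError):
            muller_index(values, "B1", "B2")

    def test_vectorized_equals_loop_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            values = random_adjusted(rng)
            i, j = rng.choice(values.index, size=2, replace=False)
            assert muller_index(values, i, j) == pytest.approx(
                muller_loop_oracle(values, i, j), abs=1e-10
            )


class TestPairwisePac:
    def test_identical_profiles_split_evenly(self):
        row = pd.Series([0.2, 0.5, 0.3], index=list("xyz"))
        assert pairwise_pac(row, row.copy()) == 0.5

    def test_disjoint_profiles_share_nothing(self):
        a = pd.Series([1.0, 0.0], index=list("xy"))
        b = pd.Series([0.0, 2.0], index=list("xy"))
        assert pairwise_pac(a, b) == 0.0

    def test_two_by_three_arithmetic(self):
        native = pd.Series([1.0, 1.0, 0.0], index=list("xyz"))
        honeybee = pd.Series([0.0, 1.0, 1.0], index=list("xyz"))
        assert pairwise_pac(native, honeybee) == pytest.approx(0.25, abs=1e-15)

    def test_invariant_to_rescaling_either_row(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = pd.Series(rng.random(8) * (rng.random(8) < 0.6))
            b = pd.Series(rng.random(8) * (rng.random(8) < 0.6))
            if a.sum() == 0:
                a[0] = 1.0
            base = pairwise_pac(a, b)
            assert pairwise_pac(a * 7.3, b) == pytest.approx(base, abs=1e-12)
            assert pairwise_pac(a, b * 0.02) == pytest.approx(base, abs=1e-12)

    def test_zero_honeybee_row_means_no_competition(self):
        a = pd.Series([1.0, 1.0], index=list("xy"))
        assert pairwise_pac(a, pd.Series([0.0, 0.0], index=list("xy"))) == 0.0


class TestPacTable:
    def _nets(self):
        """Three nearby + two distant plot networks with a shared honeybee."""
        rng = np.random.default_rng(9)
        nets = []
        for i, ptype in enumerate(["nearby"] * 3 + ["distant"] * 2):
            rows = []
            for s, sp in enumerate(["Na1", "Na2", "Na3", HONEYBEE]):
                if sp == HONEYBEE and ptype == "distant":
                    continue
                for ind in range(6):
                    plant = f"L{rng.integers(6) + 1}"
                    rows.append((f"{i}:{sp}:{ind}", sp, plant, 6))
            nets.append(
                build_network(
                    make_records(rows, plot_id=f"{ptype}_{i}", plot_type=ptype)
                )
            )
        return nets

    def test_matches_per_plot_loop(self):
        nets = self._nets()
        nearby = [n for n in nets if n.plot_type == "nearby"]
        distant = [n for n in nets if n.plot_type == "distant"]
        hb = honeybee_profile(nearby)
        nearby_adj = [adjust_matrix(n, hb) for n in nearby]
        distant_adj = [adjust_matrix(n, hb) for n in distant]
        table = pac_table(nearby_adj, distant_adj, hb)

        for sp in table.index:
            for tag, nets_adj in (("c", nearby_adj), ("d", distant_adj)):
                vals = [
                    pairwise_pac(net.values.loc[sp], hb.adjusted)
                    for net in nets_adj
                    if sp in net.values.index
                ]
                got = table.loc[sp, f"pac_{tag}"]
                if vals:
                    assert got == pytest.approx(np.mean(vals), abs=1e-12)
                    assert table.loc[sp, f"n_plots_{tag}"] == len(vals)
                else:
                    assert np.isnan(got)

    def test_species_absent_nearby_gets_missing_pac_c(self):
        nets = self._nets()
        # Remove Na3 from every nearby network to mimic local loss.
        nearby = []
        for n in nets:
            if n.plot_type != "nearby":
                continue
            counts = n.counts.drop(index="Na3", errors="ignore")
            nearby.append(
                InteractionMatrix(
                    n.plot_id, n.plot_type, counts, n.specimens.loc[counts.index]
                )
            )
        distant = [n for n in nets if n.plot_type == "distant"]
        hb = honeybee_profile(nearby)
        table = pac_table(
            [adjust_matrix(n, hb) for n in nearby],
            [adjust_matrix(n, hb) for n in distant],
            hb,
        )
        assert np.isnan(table.loc["Na3", "pac_c"])
        assert table.loc["Na3", "n_plots_c"] == 0
        assert table.loc["Na3", "pac_d"] >= 0

    def test_reverse_direction_is_symmetric(self, community):
        """Under the equal-abundance (proportion) construction the two-row
        index is symmetric: sum p*q/(p+q) does not depend on which species
        is focal, so the reverse column must mirror the headline one."""
        from beenet.pipeline import analyze_pac_change

        _, pac = analyze_pac_change(community.pollen_records, community.sweep_counts)
        for tag in ("c", "d"):
            diffs = (pac[f"pac_{tag}"] - pac[f"pac_{tag}_reverse"]).abs().dropna()
            assert (diffs < 1e-12).all()
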