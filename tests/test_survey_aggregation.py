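"""Weighted aggregation, standardization, SMR, NMR and the VIF screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neomap.survey_aggregation import (
    ArealPanel,
    aggregate,
    expected_counts,
    indicator_table,
    smr,
    vif_screen,
    weighted_nmr,
)


def records_df(rows):
    return pd.DataFrame(rows, columns=["unit_id", "period", "weight", "death"])


@pytest.fixture
def three_records():
    return records_df(
        [("A", "P1", 2.0, 1), ("A", "P1", 1.0, 0), ("A", "P1", 1.0, 0)]
    )


class TestAggregate:
    def test_weighted_sums_single_cell(self, three_records):
        panel = aggregate(three_records, ["A"], ["P1"])
        assert panel.Y[0, 0] == pytest.approx(2.0)
        assert panel.N[0, 0] == pytest.approx(4.0)

    def test_unit_weights_give_plain_counts(self, rng):
        rows = [
            (f"U{rng.integers(2)}", f"P{rng.integers(2)}", 1.0, int(rng.random() < 0.3))
            for _ in range(60)
        ]
        rec = records_df(rows)
        panel = aggregate(rec, ["U0", "U1"], ["P0", "P1"])
        for u in range(2):
            for p in range(2):
                sel = rec[(rec.unit_id == f"U{u}") & (rec.period == f"P{p}")]
                assert panel.Y[u, p] == sel.death.sum()
                assert panel.N[u, p] == len(sel)

    def test_matches_naive_per_cell_loop(self, rng):
        units, periods = ["A", "B", "C", "D"], ["P1", "P2"]
        rec = records_df(
            [
                (units[rng.integers(4)], periods[rng.integers(2)],
                 float(rng.uniform(0.1, 3)), int(rng.random() < 0.2))
                for _ in range(200)
            ]
        )
        panel = aggregate(rec, units, periods)
        for i, u in enumerate(units):
            for t, p in enumerate(periods):
                sub = rec[(rec.unit_id == u) & (rec.period == p)]
                assert panel.Y[i, t] == pytest.approx((sub.weight * sub.death).sum())
                assert panel.N[i, t] == pytest.approx(sub.weight.sum())

    def test_record_order_invariance(self, rng):
        rec = records_df(
            [("A", "P1", float(w), int(d)) for w, d in
             zip(rng.uniform(0.5, 2, 30), rng.random(30) < 0.3)]
            + [("B", "P1", 1.0, 0)]
        )
        shuffled = rec.sample(frac=1, random_state=3).reset_index(drop=True)
        p1 = aggregate(rec, ["A", "B"], ["P1"])
        p2 = aggregate(shuffled, ["A", "B"], ["P1"])
        np.testing.assert_allclose(p1.Y, p2.Y)
        np.testing.assert_allclose(p1.N, p2.N)

    def test_unknown_unit_rejected(self, three_records):
        with pytest.raises(ValueError, match="unknown units.*'A'"):
            aggregate(three_records, ["B"], ["P1"])

    def test_covariate_rules(self):
        rec = records_df(
            [("A", "P1", 1.0, 0), ("A", "P1", 1.0, 0), ("A", "P1", 2.0, 1)]
        )
        rec["rural"] = [1.0, 0.0, 1.0]
        rec["hh"] = [3.0, 5.0, 7.0]
        panel = aggregate(
            rec, ["A"], ["P1"], {"rural": "proportion", "hh": "median"}
        )
        k = panel.covariate_names.index("rural")
        assert panel.X[0, 0, k] == pytest.approx(3.0 / 4.0)  # weighted mean
        k = panel.covariate_names.index("hh")
        assert panel.X[0, 0, k] == pytest.approx(5.0)  # weighted median

    def test_empty_cells_zero_filled_with_warning(self, three_records):
        with pytest.warns(UserWarning, match="empty"):
            panel = aggregate(three_records, ["A", "B"], ["P1"])
        assert panel.Y[1, 0] == 0 and panel.N[1, 0] == 0


class TestExpectedCounts:
    def test_equal_exposure_gives_constant_e(self):
        panel = ArealPanel(["a", "b"], ["1", "2"], [[2, 4], [6, 8]], np.full((2, 2), 100.0))
        out = expected_counts(panel)
        np.testing.assert_allclose(out.E, 5.0)

    def test_unequal_exposure_direct_formula(self):
        panel = ArealPanel(
            ["a", "b"], ["1", "2"], [[2, 4], [6, 8]], [[50, 150], [200, 100]]
        )
        out = expected_counts(panel)
        np.testing.assert_allclose(out.E, [[2, 6], [8, 4]])
        np.testing.assert_allclose(smr(out), [[1, 2 / 3], [3 / 4, 2]])

    def test_single_cell_identity(self):
        panel = ArealPanel(["a"], ["1"], [[3.5]], [[70.0]])
        assert expected_counts(panel).E[0, 0] == pytest.approx(3.5)

    @given(st.integers(0, 2**32 - 1))
    def test_conservation_property(self, seed):
        r = np.random.default_rng(seed)
        I, T = int(r.integers(1, 8)), int(r.integers(1, 6))
        N = r.uniform(1, 500, (I, T))
        Y = N * r.uniform(0, 0.2, (I, T))
        out = expected_counts(ArealPanel([f"u{i}" for i in range(I)], [f"p{t}" for t in range(T)], Y, N))
        assert np.isclose(out.E.sum(), Y.sum(), rtol=1e-9)
        out.validate(standardized=True)

    def test_per_period_standardization_conserves_by_column(self):
        r = np.random.default_rng(5)
        N = r.uniform(10, 100, (4, 3))
        Y = N * r.uniform(0, 0.1, (4, 3))
        out = expected_counts(ArealPanel(list("abcd"), list("123"), Y, N), per_period=True)
        np.testing.assert_allclose(out.E.sum(axis=0), Y.sum(axis=0))

    def test_smr_zero_cases(self):
        panel = ArealPanel(["a", "b"], ["1"], [[0.0], [0.0]], [[10.0], [0.0]])
        panel = panel.replace(E=np.array([[3.0], [0.0]]))
        out = smr(panel)
        assert out[0, 0] == 0.0 and np.isnan(out[1, 0])
        bad = panel.replace(Y=np.array([[0.0], [0.0]]) + [[0], [1]],
                            N=np.array([[10.0], [1.0]]))
        with pytest.raises(ValueError, match="E=0"):
            smr(bad)


class TestWeightedNmr:
    def test_hand_arithmetic(self, three_records):
        assert weighted_nmr(three_records) == pytest.approx(500.0)  # 1000*2/4

    def test_no_deaths_zero(self):
        rec = records_df([("A", "P1", 1.5, 0), ("A", "P1", 2.0, 0)])
        assert weighted_nmr(rec) == 0.0

    def test_equal_weights_match_crude_rate(self):
        rec = records_df([("A", "P1", 1.0, int(i < 2)) for i in range(100)])
        assert weighted_nmr(rec) == pytest.approx(20.0)

    def test_period_scope_and_empty_error(self, three_records):
        assert weighted_nmr(three_records, "P1") == pytest.approx(500.0)
        with pytest.raises(ValueError, match="no records"):
            weighted_nmr(three_records, "P9")


def test_indicator_table_layout(three_records):
    rec = pd.concat(
        [three_records, records_df([("B", "P2", 1.0, 0), ("A", "P2", 1.0, 1)])],
        ignore_index=True,
    )
    with pytest.warns(UserWarning, match="empty"):
        panel = expected_counts(aggregate(rec, ["A", "B"], ["P1", "P2"]))
    table = indicator_table(rec, panel)
    assert list(table.columns) == ["period", "weighted_smr", "weighted_nmr_per_1000", "weighted_rr"]
    assert len(table) == 2
    assert table.attrs["combined_weighted_crude_nmr_per_1000"] == pytest.approx(
        1000 * 3 / 6
    )


class TestVifScreen:
    def test_collinear_column_dropped(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x + 1e-9 * rng.normal(size=50), "c": rng.normal(size=50)})
        kept, dropped = vif_screen(X)
        assert len(kept) == 2 and "c" in kept
        assert dropped[0]["vif"] > 10

    def test_orthogonal_columns_all_retained(self):
        X = pd.DataFrame(np.eye(6)[:, :3], columns=["a", "b", "c"])
        kept, dropped = vif_screen(X)
        assert kept == ["a", "b", "c"] and not dropped

    def test_matches_statsmodels_oracle(self, rng):
        base = rng.normal(size=(80, 1))
        X = pd.DataFrame(
            np.hstack([base + 0.02 * rng.normal(size=(80, 1)) for _ in range(3)]),
            columns=["x1", "x2", "x3"],
        )
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        design = sm.add_constant(X.to_numpy())
        oracle = [variance_inflation_factor(design, j + 1) for j in range(3)]
        from neomap.survey_aggregation import _vifs

        np.testing.assert_allclose(_vifs(X.to_numpy()), oracle, rtol=1e-8)

    def test_rescaling_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        X["b"] = X["a"] * 0.9 + 0.1 * X["b"]
        kept1, _ = vif_screen(X, threshold=5)
        X2 = X.copy()
        X2["a"] *= 1000.0
        kept2, _ = vif_screen(X2, threshold=5)
        assert kept1 == kept2

    def test_constant_column_dropped_first(self, rng):
        X = pd.DataFrame({"const": np.ones(30), "x": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            kept, dropped = vif_screen(X)
        assert kept == ["x"] and dropped[0]["name"] == "const"
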