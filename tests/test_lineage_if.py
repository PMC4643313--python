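"""Immunofluorescence normalization, lineage calls and treatment statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import lineagetx as lx
from lineagetx.lineage_if import ThresholdRule, anova_tukey


def _cell_table(nanog, gata6, dapi, embryo="e1", treatment="ctrl", cdx2=None):
    n = len(nanog)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "embryo_id": [embryo] * n,
            "treatment": [treatment] * n,
            "nanog": nanog,
            "gata6": gata6,
            "cdx2": cdx2 if cdx2 is not None else [10.0] * n,
            "dapi": dapi,
        }
    )


class TestNormalizeCells:
    def test_ratio(self):
        cells = _cell_table([200.0], [50.0], [100.0])
        out = lx.normalize_cells(cells)
        assert out["nanog_norm"].iloc[0] == pytest.approx(2.0)
        assert out["gata6_norm"].iloc[0] == pytest.approx(0.5)

    def test_uniform_scaling_invariance(self):
        cells = _cell_table([200.0, 30.0], [50.0, 60.0], [100.0, 120.0])
        scaled = cells.copy()
        for ch in ("nanog", "gata6", "cdx2", "dapi"):
            scaled[ch] = scaled[ch] * 3.7
        a, b = lx.normalize_cells(cells), lx.normalize_cells(scaled)
        for ch in ("nanog_norm", "gata6_norm", "cdx2_norm"):
            np.testing.assert_allclose(a[ch], b[ch])

    def test_zero_dapi_dropped_and_counted(self):
        cells = _cell_table([200.0, 100.0], [50.0, 40.0], [100.0, 0.0])
        out = lx.normalize_cells(cells)
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1


class TestCallPositive:
    def test_fixed_rule_boundary(self):
        t = 1.0
        cells = lx.normalize_cells(
            _cell_table([100.0 * (t + 1e-6), 100.0 * (t - 1e-6)], [1.0, 1.0], [100.0, 100.0])
        )
        calls = lx.call_positive(cells, "nanog", ThresholdRule("fixed", threshold=t))
        assert calls.tolist() == [True, False]

    def test_bimodal_modes_recovered(self):
        """Two well-separated log-normal modes: calls match the planted
        labels for at least 99% of cells."""
        rng = np.random.default_rng(0)
        n = 2000
        positive = rng.random(n) < 0.4
        intensity = np.where(
            positive,
            np.exp(rng.normal(np.log(800), 0.25, n)),
            np.exp(rng.normal(np.log(20), 0.25, n)),
        )
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "embryo_id": np.repeat([f"e{j}" for j in range(10)], n // 10),
                "treatment": "ctrl",
                "nanog": intensity,
                "gata6": 10.0,
                "cdx2": 10.0,
                "dapi": np.exp(rng.normal(np.log(1000), 0.2, n)),
            }
        )
        calls = lx.call_positive(lx.normalize_cells(cells), "nanog")
        assert (calls.to_numpy() == positive).mean() >= 0.99

    def test_all_equal_intensities_all_negative(self):
        cells = lx.normalize_cells(
            _cell_table([50.0] * 5, [1.0] * 5, [100.0] * 5)
        )
        calls = lx.call_positive(cells, "nanog")
        assert not calls.any()

    def test_tiny_embryo_falls_back_to_global(self):
        rng = np.random.default_rng(1)
        big = _cell_table(
            list(np.exp(rng.normal(np.log(800), 0.2, 30))) + list(np.exp(rng.normal(np.log(20), 0.2, 30))),
            [1.0] * 60,
            [100.0] * 60,
            embryo="big",
        )
        tiny = _cell_table([800.0, 20.0], [1.0, 1.0], [100.0, 100.0], embryo="tiny")
        tiny["cell_id"] = ["t0", "t1"]
        cells = lx.normalize_cells(pd.concat([big, tiny], ignore_index=True))
        calls = lx.call_positive(cells, "nanog")
        sub = calls[cells["embryo_id"] == "tiny"]
        assert sub.tolist() == [True, False]


class TestClassifyLineage:
    def _classified(self, nanog_pos, gata6_pos, nanog_norm):
        n = len(nanog_pos)
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "embryo_id": "e1",
                "treatment": "ctrl",
                "nanog_norm": nanog_norm,
                "gata6_norm": 0.5,
            }
        )
        return lx.classify_lineage(
            cells,
            pd.Series(nanog_pos, index=cells.index),
            pd.Series(gata6_pos, index=cells.index),
        )

    def test_class_definitions(self):
        out = self._classified(
            [True, False, True, False], [False, True, True, False], [2.0, 0.1, 1.0, 0.1]
        )
        assert out["lineage_class"].tolist() == [
            "NANOG-only",
            "GATA6-only",
            "coexpressing",
            "double-negative",
        ]

    def test_nanog_high_inclusive_at_exactly_1_5x(self):
        # embryo mean nanog_norm = 1.0; the 1.5 value is exactly 1.5x -> high
        out = self._classified(
            [True, True, True, True], [False] * 4, [1.5, 1.0, 1.0, 0.5]
        )
        assert bool(out["nanog_high"].iloc[0]) is True
        assert out["nanog_high"].iloc[1:].sum() == 0

    def test_nanog_high_requires_positivity(self):
        out = self._classified([False, True], [False, False], [10.0, 0.1])
        assert bool(out["nanog_high"].iloc[0]) is False

    def test_classes_partition_cells(self, if_cells_null):
        cells, _ = if_cells_null
        calls = lx.classify_lineage(lx.normalize_cells(cells))
        assert calls["lineage_class"].isin(lx.lineage_if.LINEAGE_CLASSES).all()

    def test_embryo_scaling_changes_no_call(self, if_cells_null):
        cells, _ = if_cells_null
        scaled = cells.copy()
        mask = scaled["embryo_id"] == scaled["embryo_id"].iloc[0]
        for ch in ("nanog", "gata6", "cdx2", "dapi"):
            scaled.loc[mask, ch] *= 4.2
        a = lx.classify_lineage(lx.normalize_cells(cells))
        b = lx.classify_lineage(lx.normalize_cells(scaled))
        assert (a["lineage_class"] == b["lineage_class"]).all()
        assert (a["nanog_high"] == b["nanog_high"]).all()


class TestEmbryoProportions:
    def test_counting(self):
        calls = pd.DataFrame(
            {
                "embryo_id": ["e1"] * 10,
                "treatment": "ctrl",
                "lineage_class": ["NANOG-only"] * 4 + ["GATA6-only"] * 6,
                "nanog_high": [True] + [False] * 9,
            }
        )
        props = lx.embryo_proportions(calls)
        assert props.loc["e1", "frac_NANOG-only"] == pytest.approx(0.4)
        assert props.loc["e1", "n_cells"] == 10

    def test_fractions_sum_to_one(self, if_cells_null):
        cells, _ = if_cells_null
        calls = lx.classify_lineage(lx.normalize_cells(cells))
        props = lx.embryo_proportions(calls)
        frac_cols = [f"frac_{c}" for c in lx.lineage_if.LINEAGE_CLASSES]
        np.testing.assert_allclose(props[frac_cols].sum(axis=1), 1.0, atol=1e-12)

    def test_planted_doubling_recovered(self):
        """A treatment with doubled NANOG-only probability shows a class
        fraction ratio of ~2 in the planted truth at large n."""
        effects = {"T": lx.TreatmentEffect(class_weight={"NANOG-only": 2.0})}
        cells, truth = lx.simulate_if_cells(2, 2500, ["C", "T"], effects, seed=9)
        merged = cells.merge(truth, left_on="cell_id", right_index=True)
        frac = merged.groupby("treatment")["true_class"].apply(
            lambda s: (s == "NANOG-only").mean()
        )
        # doubled weight then renormalized: 0.5/1.25 vs 0.25
        assert frac["T"] / frac["C"] == pytest.approx(1.6, abs=0.15)


# ---------------------------------------------------------------------------
# ANOVA / Tukey
# ---------------------------------------------------------------------------

def studentized_range_sf_oracle(q, k, df):
    """Numerical integration of the studentized-range distribution."""

    def inner(u):
        # probability that the range of k standard normals is <= u
        f = lambda z: stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - u)) ** (k - 1)
        val, _ = quad(f, -8.0, 8.0, limit=200)
        return k * val

    # s = sqrt(chi2_df / df) density
    log_c = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0) + math.log(2.0)

    def outer(s):
        return math.exp(log_c + (df - 1) * math.log(s) - df * s * s / 2.0) * inner(q * s)

    cdf, _ = quad(outer, 1e-9, 8.0, limit=200)
    return 1.0 - cdf


class TestAnovaTukey:
    def test_identical_groups_null_boundary(self):
        vals = pd.Series([3.0] * 9)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = anova_tukey(vals, groups)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert (res.pairwise["p_adj"] == 1.0).all()

    def test_two_groups_match_pooled_t_test(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        res = anova_tukey(
            pd.Series(np.r_[a, b]), pd.Series(["a"] * 5 + ["b"] * 6)
        )
        _, p_t = stats.ttest_ind(a, b)
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-10)

    def test_matches_quadrature_oracle(self):
        """Tukey p for a planted shift agrees with direct numerical
        integration of the studentized-range distribution."""
        rng = np.random.default_rng(7)
        vals = np.r_[rng.normal(0, 1, 4), rng.normal(1.5, 1, 4), rng.normal(0.5, 1, 4)]
        groups = pd.Series(np.repeat(["a", "b", "c"], 4))
        res = anova_tukey(pd.Series(vals), groups)
        for _, row in res.pairwise.iterrows():
            want = studentized_range_sf_oracle(row["q"], k=3, df=res.df_within)
            assert row["p_adj"] == pytest.approx(want, abs=1e-4)

    def test_zero_variance_unequal_means_floored(self):
        vals = pd.Series([1.0, 1.0, 2.0, 2.0])
        groups = pd.Series(["a", "a", "b", "b"])
        res = anova_tukey(vals, groups)
        assert res.p_value <= 1e-15

    def test_underreplicated_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))


class TestSimulateIfCells:
    def test_determinism(self):
        a, ta = lx.simulate_if_cells(2, 20, ["C", "T"], seed=5)
        b, tb = lx.simulate_if_cells(2, 20, ["C", "T"], seed=5)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_null_effects_balance_class_proportions(self, if_cells_null):
        cells, truth = if_cells_null
        merged = cells.merge(truth, left_on="cell_id", right_index=True)
        frac = merged.groupby("treatment")["true_class"].apply(
            lambda s: (s == "NANOG-only").mean()
        )
        assert abs(frac.iloc[0] - frac.iloc[1]) < 0.1

    def test_channel_mean_shift(self):
        effects = {"T": lx.TreatmentEffect(channel_scale={"NANOG": 2.0})}
        cells, _ = lx.simulate_if_cells(2, 2500, ["C", "T"], effects, seed=13)
        means = cells.groupby("treatment")["nanog"].mean()
        assert means["T"] / means["C"] == pytest.approx(2.0, rel=0.1)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            lx.TreatmentEffect(channel_scale={"SOX17": 2.0})
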