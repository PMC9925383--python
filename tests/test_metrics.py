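import numpy as np
import pandas as pd
import pytest

from conftest import make_readset
from transtress.annotation import GeneModel
from transtress.metrics import (
    density_change_percent,
    elongation_phase,
    first_last_exon_loss,
    gene_body_decline_by_class,
    length_classes,
    per_kb_loss_slope,
    select_ts_high,
    three_bin_heatmap,
    travel_ratio,
    utr3_abundance,
)


def frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.index.name = "gene_id"
    df.columns = [f"bin_{i + 1}" for i in range(df.shape[1])]
    return df


class TestDensityChange:
    def test_simple_ratio(self):
        dc = density_change_percent(frame({"g": [8.0]}), frame({"g": [10.0]}))
        assert dc.per_gene.iloc[0, 0] == pytest.approx(80.0)

    def test_self_comparison_is_identity(self):
        m = frame({"a": [1, 2, 3], "b": [4, 5, 6]})
        dc = density_change_percent(m, m)
        assert np.allclose(dc.per_gene.to_numpy(), 100.0)
        assert np.allclose(dc.bin_mean.to_numpy(), 100.0)

    def test_three_gene_toy_matches_hand_computation(self):
        old = frame({"a": [4, 2], "b": [9, 3], "c": [1, 0]})
        adult = frame({"a": [8, 4], "b": [3, 6], "c": [2, 1]})
        dc = density_change_percent(old, adult)
        expect = np.array([[50.0, 50.0], [300.0, 50.0], [50.0, 0.0]])
        assert np.allclose(dc.per_gene.to_numpy(), expect)

    def test_zero_adult_bins_masked(self):
        dc = density_change_percent(frame({"g": [5.0, 5.0]}), frame({"g": [0.0, 10.0]}))
        assert np.isnan(dc.per_gene.iloc[0, 0]) and dc.per_gene.iloc[0, 1] == 50.0


class TestElongationPhase:
    def test_default_20_bins_keep_18(self):
        assert len(elongation_phase(np.arange(20))) == 18

    def test_generalizes_to_any_k(self):
        assert len(elongation_phase(np.arange(5))) == 3

    def test_reapplication_shrinks_further(self):
        once = elongation_phase(np.arange(20))
        assert len(elongation_phase(once)) == 16

    def test_dataframe_drops_terminal_columns(self):
        df = frame({"g": list(range(20))})
        out = elongation_phase(df)
        assert list(out.columns) == [f"bin_{i}" for i in range(2, 20)]


class TestThreeBinHeatmap:
    def test_equal_groups_give_zero(self):
        m = frame({"g": [1.0] * 18})
        assert np.allclose(three_bin_heatmap(m, m).to_numpy(), 0.0)

    def test_doubling_gives_plus_one(self):
        m = frame({"g": list(range(1, 19))})
        assert np.allclose(three_bin_heatmap(2 * m, m, pseudocount=0).to_numpy(), 1.0)

    def test_linear_decline_gives_decreasing_triple(self):
        ratio = np.linspace(1.0, 0.65, 18)
        old = frame({"g": ratio.tolist()})
        adult = frame({"g": [1.0] * 18})
        vals = three_bin_heatmap(old, adult, pseudocount=0).to_numpy()[0]
        assert vals[0] > vals[1] > vals[2]


class TestTravelRatio:
    def _gene(self):
        return GeneModel("g", "chr1", "+", 5_000, 45_000)

    def test_worked_arithmetic(self):
        # 20 reads in TSS±300 (600 bp), 5 in [TSS+300, TSS+1300) (1 kb)
        tss_mids = np.linspace(4_710, 5_290, 20).astype(int)
        body_mids = np.linspace(5_310, 6_290, 5).astype(int)
        rs = make_readset(np.r_[tss_mids, body_mids], width=2, assay="ChIP_total")
        tr = travel_ratio(rs, self._gene())
        assert tr == pytest.approx((20 / 600) / (5 / 1000), rel=1e-9)

    def test_uniform_coverage_is_one(self):
        mids = np.arange(4_700, 6_300)  # one read per bp over both regions
        rs = make_readset(mids, width=2, assay="ChIP_total")
        assert travel_ratio(rs, self._gene()) == pytest.approx(1.0)

    def test_zero_denominator_masked(self):
        rs = make_readset([5_000], width=2, assay="ChIP_total")  # TSS window only
        assert np.isnan(travel_ratio(rs, self._gene()))


class TestLengthClasses:
    def test_fixed_boundary_convention(self):
        lengths = pd.Series({"a": 21_999, "b": 22_000})
        classes = length_classes(lengths, mode="fixed_bounds")
        assert classes.labels["a"] == 0 and classes.labels["b"] == 1

    def test_quantile_mode_balances(self):
        rng = np.random.default_rng(0)
        lengths = pd.Series(rng.integers(10_000, 300_000, size=60), index=[f"g{i}" for i in range(60)])
        classes = length_classes(lengths, mode="quantile6")
        assert (classes.summary["n"] == 10).all()

    def test_classes_partition_the_input(self):
        lengths = pd.Series(np.linspace(10_000, 299_000, 37), index=[f"g{i}" for i in range(37)])
        classes = length_classes(lengths)
        assert classes.labels.notna().all()
        assert int(classes.summary["n"].sum()) == 37


class TestLossSlope:
    def test_collinear_points_recover_035(self):
        summary = pd.DataFrame(
            {"mean_length_kb": [20.0, 60.0, 100.0], "decline_percent": [7.0, 21.0, 35.0]}
        )
        slope, se = per_kb_loss_slope(summary)
        assert slope == pytest.approx(0.35, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_equal_declines_give_zero_slope(self):
        summary = pd.DataFrame(
            {"mean_length_kb": [20.0, 60.0, 100.0], "decline_percent": [10.0, 10.0, 10.0]}
        )
        assert per_kb_loss_slope(summary)[0] == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self):
        summary = pd.DataFrame(
            {"mean_length_kb": [20.0, 60.0, 100.0], "decline_percent": [5.0, 22.0, 33.0]}
        )
        shuffled = summary.iloc[[2, 0, 1]]
        assert per_kb_loss_slope(summary)[0] == pytest.approx(per_kb_loss_slope(shuffled)[0])

    def test_too_few_classes_error(self):
        summary = pd.DataFrame({"mean_length_kb": [20.0, 60.0], "decline_percent": [7.0, 21.0]})
        with pytest.raises(ValueError):
            per_kb_loss_slope(summary)

    def test_decline_extrapolation_recovers_linear_survival(self):
        # a pure (1 - beta*x) old/adult curve must yield 100*beta*L per class
        beta = 0.0035
        k = 20
        rel_mid = (np.arange(k) + 0.5) / k
        lengths = pd.Series({"a": 80_000, "b": 80_000})
        pct = 100 * (1 - beta * rel_mid * 80)
        change = density_change_percent(
            frame({"a": pct.tolist(), "b": pct.tolist()}),
            frame({"a": [100.0] * k, "b": [100.0] * k}),
        )
        classes = length_classes(lengths.astype(float), mode="quantile6")
        decline = gene_body_decline_by_class(change, lengths, classes)
        got = decline.dropna(subset=["decline_percent"])
        assert got["decline_percent"].iloc[0] == pytest.approx(100 * beta * 80, rel=1e-6)


class TestExonMetrics:
    def _tables(self, adult_first, adult_last, old_first, old_last):
        idx = pd.Index(["g"], name="gene_id")
        lengths = pd.DataFrame({"first_exon": [100], "last_exon": [200], "utr3": [100]}, index=idx)
        mk = lambda f, l: pd.DataFrame(  # noqa: E731
            {"first_exon": [f], "last_exon": [l], "utr3": [l / 2]}, index=idx
        )
        return {"adult": [mk(adult_first, adult_last)], "old": [mk(old_first, old_last)]}, lengths

    def test_worked_fold(self):
        # adult r = (160/200)/(100/100) = 0.8 ; old r = 0.5333 -> fold 1.5
        tables, lengths = self._tables(100, 160, 100, 106.667)
        out = first_last_exon_loss(tables, lengths)
        assert out.loc["g", "loss_fold"] == pytest.approx(1.5, rel=1e-4)

    def test_identity_fold_is_one(self):
        tables, lengths = self._tables(50, 80, 50, 80)
        assert first_last_exon_loss(tables, lengths).loc["g", "loss_fold"] == pytest.approx(1.0)

    def test_sample_scaling_leaves_r_unchanged(self):
        t1, lengths = self._tables(50, 80, 50, 80)
        t2, _ = self._tables(100, 160, 50, 80)  # doubled adult sample
        a = first_last_exon_loss(t1, lengths)
        b = first_last_exon_loss(t2, lengths)
        assert a.loc["g", "r_adult"] == pytest.approx(b.loc["g", "r_adult"])

    def test_utr3_ratio(self):
        tables, lengths = self._tables(100, 100, 100, 65.0)
        ratio, _ = utr3_abundance(tables, lengths)
        assert ratio["g"] == pytest.approx(0.65)


class TestTsHighSelection:
    def test_strict_threshold(self):
        folds = pd.Series({"a": 1.0, "b": 1.4, "c": 1.5, "d": 1.6, "e": 2.0})
        assert select_ts_high(folds) == {"d", "e"}

    def test_infinite_threshold_empty(self):
        folds = pd.Series({"a": 10.0})
        assert select_ts_high(folds, threshold=np.inf) == set()

    def test_monotone_in_threshold(self):
        folds = pd.Series(np.linspace(0.5, 3.0, 20), index=[f"g{i}" for i in range(20)])
        prev = None
        for thr in (1.0, 1.5, 2.0, 2.5):
            cur = select_ts_high(folds, threshold=thr)
            if prev is not None:
                assert cur <= prev
            prev = cur
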