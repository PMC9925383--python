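import numpy as np
import pandas as pd
import pytest

from transtress import SimConfig
from transtress.annotation import filter_unique_genes
from transtress.metrics import length_classes
from transtress.profiling import bin_gene_body
from transtress.simulate import (
    calibrate_stalled_read_weight,
    expected_eu_bins,
    place_lesions,
    read_dataset,
    readset_from_bins,
    simulate_archetype_features,
    simulate_catalog,
    simulate_chip_profile,
    simulate_dataset,
    simulate_eu_profile,
    write_dataset,
)


class TestCatalog:
    def test_determinism(self):
        cfg = SimConfig(seed=1, n_genes=10)
        a = simulate_catalog(cfg, np.random.default_rng(1))
        b = simulate_catalog(cfg, np.random.default_rng(1))
        assert [(g.gene_id, g.start, g.end, g.strand, g.exons) for g in a] == [
            (g.gene_id, g.start, g.end, g.strand, g.exons) for g in b
        ]

    def test_lengths_within_range_and_structure(self, default_sim):
        for g in default_sim.catalog:
            assert 10_000 <= g.length <= 300_000
            assert len(g.exons) >= 2
            assert g.utr3 is not None

    def test_genes_pass_the_uniqueness_filter(self, default_sim):
        filtered = filter_unique_genes(default_sim.catalog)
        assert len(filtered) == len(default_sim.catalog)

    def test_six_quantile_classes_balance(self):
        cfg = SimConfig(seed=3, n_genes=60)
        cat = simulate_catalog(cfg, np.random.default_rng(3))
        lengths = pd.Series({g.gene_id: g.length for g in cat})
        classes = length_classes(lengths, mode="quantile6")
        assert ((classes.summary["n"] - 10).abs() <= 1).all()


class TestLesions:
    def test_zero_density_places_nothing(self, toy_gene):
        rng = np.random.default_rng(0)
        assert len(place_lesions(toy_gene, 0.0, rng)) == 0

    def test_poisson_mean_and_variance(self):
        # 10,000 draws for a 100-kb gene at 1.6/100kb diploid: template
        # allele mean 0.8, and Poisson variance ~ mean.
        from transtress.annotation import GeneModel

        g = GeneModel("g", "chr1", "+", 0, 100_000)
        rng = np.random.default_rng(42)
        counts = np.array([len(place_lesions(g, 1.6, rng)) for _ in range(10_000)])
        se = np.sqrt(0.8 / len(counts))
        assert abs(counts.mean() - 0.8) < 3 * se
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_offsets_inside_gene(self, toy_gene):
        offs = place_lesions(toy_gene, 50.0, np.random.default_rng(1))
        assert len(offs) > 0
        assert (offs >= 0).all() and (offs < toy_gene.length).all()


class TestEuProfile:
    def test_no_excess_loss_means_equal_groups(self, toy_gene):
        cfg = SimConfig(old_excess_loss_per_kb=0.0)
        a = expected_eu_bins(toy_gene, 0.01, cfg, "adult")
        o = expected_eu_bins(toy_gene, 0.01, cfg, "old")
        assert np.allclose(o / a, 1.0)

    def test_ratio_at_100kb_is_065(self):
        from transtress.annotation import GeneModel

        g = GeneModel("g", "chr1", "+", 0, 200_000)
        cfg = SimConfig(old_excess_loss_per_kb=0.35, k=20)
        a = expected_eu_bins(g, 0.01, cfg, "adult")
        o = expected_eu_bins(g, 0.01, cfg, "old")
        # bin 10 midpoint sits at 0.525 * 200 kb = 105 kb; interpolate to 100 kb
        mid_kb = (np.arange(20) + 0.5) / 20 * 200
        ratio = np.interp(100.0, mid_kb, o / a)
        assert ratio == pytest.approx(0.65, abs=1e-9)

    def test_counts_deterministic_under_seed(self, toy_gene):
        cfg = SimConfig(seed=5)
        _, c1 = simulate_eu_profile(toy_gene, 0.01, cfg, "old", np.random.default_rng(5))
        _, c2 = simulate_eu_profile(toy_gene, 0.01, cfg, "old", np.random.default_rng(5))
        assert (c1 == c2).all()

    def test_mean_counts_match_survival_model(self, default_sim):
        # closed-form agreement: per-bin totals across genes/replicates vs
        # the linear survival expectation, within Poisson error.
        cfg = default_sim.config
        for group in ("adult", "old"):
            expected = np.zeros(cfg.k)
            for g in default_sim.catalog:
                expected += expected_eu_bins(g, default_sim.expression[g.gene_id], cfg, group)
                expected += cfg.intergenic_rate * g.length / cfg.k
            expected *= cfg.n_replicates
            observed = sum(
                p.data.to_numpy().sum(axis=0)
                for p in default_sim.eu_profiles()
                if p.group == group
            )
            z = (observed - expected) / np.sqrt(expected)
            assert np.abs(z).max() < 4.0


class TestChipProfile:
    def test_no_stalling_no_lesions_equal_expectation(self, toy_gene):
        cfg = SimConfig(stalling_target_percent=0.0)
        rng = np.random.default_rng(0)
        a = simulate_chip_profile(toy_gene, 0.01, cfg, "adult", rng)
        o = simulate_chip_profile(toy_gene, 0.01, cfg, "old", rng, stall_factor=0.0)
        # old productive tracks old nascent density; with s=0 no excess:
        ratio = o["expected_total"] / a["expected_total"]
        mid_kb = (np.arange(cfg.k) + 0.5) / cfg.k * toy_gene.length / 1000
        assert np.allclose(ratio, 1 - 0.0035 * mid_kb, atol=1e-9)

    def test_queue_point_mass_at_lesion_bin(self, toy_gene):
        cfg = SimConfig(mode="mechanistic", queue_size=3, intergenic_rate=0.0)
        lesion = np.array([toy_gene.length // 2])
        res = simulate_chip_profile(
            toy_gene, 0.0, cfg, "old", np.random.default_rng(0), lesions=lesion, stall_weight=1.0
        )
        k = cfg.k
        b = int(lesion[0] * k // toy_gene.length)
        total = res["expected_total"]
        # (1 + queue_size) complexes, template dropout removes p/2 of reads
        assert total[b] == pytest.approx(4 * (1 - cfg.template_dropout / 2))
        assert np.count_nonzero(total) == 1

    def test_no_dropout_keeps_strands_balanced(self, toy_gene):
        cfg = SimConfig(mode="mechanistic", template_dropout=0.0, intergenic_rate=0.0)
        lesions = np.sort(np.random.default_rng(2).integers(0, toy_gene.length, 50))
        res = simulate_chip_profile(
            toy_gene, 0.05, cfg, "old", np.random.default_rng(3), lesions=lesions, stall_weight=5.0
        )
        c, t = res["coding"].sum(), res["template"].sum()
        frac = c / (c + t)
        se = 0.5 / np.sqrt(c + t)
        assert abs(frac - 0.5) < 4 * se

    def test_calibration_hits_target_excess(self, mech_sim):
        cfg = mech_sim.config
        w = mech_sim.ground_truth["stall_read_weight"]
        prod = sum(
            cfg.chip_scale * expected_eu_bins(g, mech_sim.expression[g.gene_id], cfg, "old").sum()
            for g in mech_sim.catalog
        )
        stalled = (
            w
            * mech_sim.lesions.total()
            * (1 + cfg.queue_size)
            * (1 - cfg.template_dropout / 2)
        )
        assert 100 * stalled / prod == pytest.approx(cfg.stalling_target_percent, abs=2.0)


class TestDatasetRoundTrip:
    def test_write_read_and_byte_determinism(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=15)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_dataset(cfg), d1)
        write_dataset(simulate_dataset(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
        loaded = read_dataset(d1)
        orig = simulate_dataset(cfg)
        assert len(loaded.profiles) == (2 * cfg.n_replicates) * 2  # EU + ChIP
        for p, q in zip(orig.profiles, loaded.profiles):
            pd.testing.assert_frame_equal(p.data, q.data, check_dtype=False)
        assert loaded.config == cfg

    def test_refuses_to_overwrite(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=5)
        out = tmp_path / "d"
        write_dataset(simulate_dataset(cfg), out)
        with pytest.raises(FileExistsError):
            write_dataset(simulate_dataset(cfg), out)

    def test_reads_rebin_to_the_same_matrix(self, tmp_path):
        cfg = SimConfig(seed=13, n_genes=8, expression_median=0.002)
        ds = simulate_dataset(cfg)
        profile = ds.eu_profiles()[0]
        rs = readset_from_bins(ds.catalog, profile, np.random.default_rng(0))
        rebinned = bin_gene_body(rs, ds.catalog, k=cfg.k)
        pd.testing.assert_frame_equal(rebinned, profile.data, check_dtype=False)


def test_archetype_features_shape_and_lengths():
    feats, labels, lengths = simulate_archetype_features(50, rng=np.random.default_rng(1))
    assert feats.shape == (200, 6)
    assert set(labels) == {"promoter_up", "promoter_down", "glpt_high", "remainder"}
    assert (
        lengths[labels == "glpt_high"].mean() > lengths[labels == "remainder"].mean()
    )
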