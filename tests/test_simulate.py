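"""The sequential-immunoprecipitation simulator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from rebivalent.intervals import read_fragments
from rebivalent.simulate import (CapacityError, EmptyPoolError,
                                 PLAN_IGG_IGG, PLAN_K4K27, PLAN_K27K4,
                                 PLAN_TOTAL_K4, SimulatorConfig, STATES,
                                 TruthMap, build_truth, make_study,
                                 sample_seed, simulate_sample)

from conftest import small_config


class TestConfigValidation:
    def test_specific_capture_must_beat_background(self):
        with pytest.raises(ValueError, match="capture_specific"):
            SimulatorConfig(seed=1, capture_specific=0.002,
                            capture_nonspecific=0.003)

    def test_region_width_floor(self):
        with pytest.raises(ValueError, match="nucleosome_spacing"):
            SimulatorConfig(seed=1, region_width_range=(100, 500))

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="outside"):
            SimulatorConfig(seed=1, mark_prob=1.5)


class TestBuildTruth:
    def test_empty_region_counts(self):
        cfg = small_config(region_counts={})
        t = build_truth(cfg)
        assert len(t.regions) == 0

    def test_deterministic(self):
        cfg = small_config(seed=1)
        a, b = build_truth(cfg), build_truth(cfg)
        pd.testing.assert_frame_equal(a.regions, b.regions)

    def test_counts_and_geometry(self, truth, sim_config):
        counts = truth.regions["state"].value_counts().to_dict()
        assert counts == sim_config.region_counts
        widths = truth.regions["end"] - truth.regions["start"]
        assert widths.sum() <= sim_config.genome_length
        lo, hi = sim_config.region_width_range
        assert widths.between(lo, hi).all()
        # non-overlapping with >= 2 fragment lengths clearance, sorted
        gap = 2 * sim_config.fragment_length
        for _, sub in truth.regions.groupby("chrom"):
            s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (np.diff(s) > 0).all()
            assert (s[1:] - e[:-1] >= gap).all()

    def test_capacity_error_on_tiny_genome(self):
        cfg = small_config(chrom_length=20_000)
        with pytest.raises(CapacityError):
            build_truth(cfg)

    def test_dko_dependent_flag_is_seeded_subset_of_bivalent(self, truth,
                                                             sim_config):
        dep = truth.regions[truth.regions["dko_dependent"]]
        assert (dep["state"] == "BIVALENT").all()
        n_biv = sim_config.region_counts["BIVALENT"]
        assert len(dep) == round(sim_config.dko_dependent_fraction * n_biv)

    def test_truth_bed_round_trip(self, truth, tmp_path):
        p = tmp_path / "truth.bed"
        truth.write_bed(p)
        back = TruthMap.read_bed(p, truth.chrom_sizes)
        pd.testing.assert_frame_equal(back.regions, truth.regions)


def _density(frags, regions):
    """Fragments per covered base."""
    n = regions.count_overlaps(frags).sum()
    return n / regions.total_bases()


class TestSimulateSample:
    def test_deterministic(self, truth, sim_config):
        a = simulate_sample(truth, sim_config, PLAN_K4K27, seed=9)
        b = simulate_sample(truth, sim_config, PLAN_K4K27, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_rechip_blind_to_heterogeneity(self, truth, sim_config, samples):
        """Two-round capture enriches truly bivalent regions an order of
        magnitude over allelic/cellular heterogeneity."""
        frags = samples["k4k27"]
        biv = truth.by_state("BIVALENT")
        het = truth.by_state("ALLELIC_HET", "CELLULAR_HET")
        assert _density(frags, biv) >= 10 * _density(frags, het)

    def test_heterogeneity_alone_gives_no_rechip_survivors(self):
        """With zero background marks, a reChIP on a genome containing only
        heterogeneous regions yields orders of magnitude fewer fragments
        than the same plan on bivalent-only truth."""
        base = dict(seed=5, background_mark_prob=0.0, depth=1_000_000_000)
        het_cfg = small_config(region_counts={"ALLELIC_HET": 20,
                                              "CELLULAR_HET": 20}, **base)
        biv_cfg = small_config(region_counts={"BIVALENT": 40}, **base)
        het_n = simulate_sample(build_truth(het_cfg), het_cfg,
                                PLAN_K4K27, seed=1).library_size
        biv_n = simulate_sample(build_truth(biv_cfg), biv_cfg,
                                PLAN_K4K27, seed=1).library_size
        assert het_n * 20 < biv_n

    def test_single_chip_blindness(self, truth, sim_config, samples):
        """A single ChIP cannot separate heterogeneity from bivalency: under
        [K4] alone, heterogeneous and bivalent regions are comparably
        enriched (within 2x after accounting for the mark dose)."""
        frags = samples["k4_total"]
        biv = truth.by_state("BIVALENT")
        het = truth.by_state("ALLELIC_HET", "CELLULAR_HET")
        # half the alleles/cells carry K4 in het regions vs all in bivalent
        ratio = _density(frags, biv) / (2 * _density(frags, het))
        assert 0.5 <= ratio <= 2.0

    def test_igg_second_ip_subsamples_first(self):
        # at full default depth: IgG as a second antibody merely subsamples
        # the first enrichment, so per-region proportions mirror it
        cfg = SimulatorConfig(seed=41)
        t = build_truth(cfg)
        k4 = simulate_sample(t, cfg, PLAN_TOTAL_K4, seed=61)
        k4igg = simulate_sample(t, cfg, ("K4", "IGG"), seed=62)
        regions = t.to_interval_set()
        a = regions.count_overlaps(k4) / k4.library_size
        b = regions.count_overlaps(k4igg) / k4igg.library_size
        assert np.corrcoef(a, b)[0, 1] > 0.9

    def test_taz_mode_depletes_rechip_both_orientations(self, truth,
                                                        sim_config, samples):
        taz_cfg = small_config(seed=sim_config.seed, mode="TAZ")
        biv = truth.by_state("BIVALENT")
        for plan, wt_key in ((PLAN_K4K27, "k4k27"), (PLAN_K27K4, "k27k4")):
            taz = simulate_sample(truth, taz_cfg, plan, seed=71)
            wt = samples[wt_key]
            # absolute recovery at bivalent regions collapses (what a
            # reChIP-qPCR reads out), as does the total pulled-down yield
            assert biv.count_overlaps(taz).sum() \
                < biv.count_overlaps(wt).sum() / 10
            assert taz.library_size < wt.library_size / 3

    def test_dko_mode_erases_dependent_regions_only(self, truth):
        cfg = small_config(mode="DKO", depth=1_000_000_000)
        frags = simulate_sample(truth, cfg, PLAN_K4K27, seed=81)
        dep = truth.dko_dependent()
        stable = truth.by_state("BIVALENT").df.merge(
            dep.df, how="left", indicator=True,
            on=["chrom", "start", "end"])
        from rebivalent.intervals import IntervalSet
        stable = IntervalSet(stable[stable["_merge"] == "left_only"]
                             [["chrom", "start", "end"]])
        assert _density(frags, dep) < _density(frags, stable) / 20

    def test_empty_pool_error_names_stage(self):
        cfg = small_config(region_counts={}, background_mark_prob=0.0,
                           capture_nonspecific=0.0, carryover=0.0)
        t = build_truth(cfg)
        with pytest.raises(EmptyPoolError, match="first immunoprecipitation"):
            simulate_sample(t, cfg, PLAN_TOTAL_K4, seed=1)

    def test_plan_validation(self, truth, sim_config):
        with pytest.raises(ValueError, match="one or two"):
            simulate_sample(truth, sim_config, ("K4", "K27", "K4"))
        with pytest.raises(ValueError, match="unknown antibody"):
            simulate_sample(truth, sim_config, ("H3",))


class TestParameterRecovery:
    def test_capture_rates_recoverable_from_pure_regions(self):
        """Observed capture fractions in K4-only regions and background
        recover the specific and nonspecific capture probabilities within
        20%."""
        cfg = small_config(seed=17, depth=1_000_000_000)
        t = build_truth(cfg)
        frags = simulate_sample(t, cfg, PLAN_TOTAL_K4, seed=17)
        trials = cfg.n_cells * cfg.ploidy
        k4 = t.by_state("K4_ONLY")
        n_pos_k4 = sum((row.end - row.start) // cfg.nucleosome_spacing
                       for row in k4.df.itertuples(index=False))
        p_hat = k4.count_overlaps(frags).sum() / (n_pos_k4 * trials)
        # per-trial capture prob in a K4-only region: m*e + (1-m)*b
        bg_bases = cfg.genome_length - t.regions["end"].sub(
            t.regions["start"]).sum()
        n_pos_bg = cfg.genome_length // cfg.nucleosome_spacing - sum(
            (row.end - row.start) // cfg.nucleosome_spacing
            for row in t.regions.itertuples(index=False))
        bg_count = frags.library_size - t.to_interval_set().count_overlaps(
            frags).sum()
        b_hat = bg_count / (n_pos_bg * trials)  # ~ eps*e + b
        e_hat = (p_hat - (1 - cfg.mark_prob) * b_hat) / cfg.mark_prob
        assert abs(e_hat - cfg.capture_specific) / cfg.capture_specific < 0.2
        assert abs(b_hat - cfg.capture_nonspecific) \
            / cfg.capture_nonspecific < 0.2


class TestMakeStudy:
    def test_file_layout_and_determinism(self, tmp_path):
        cfg = small_config(seed=23, depth=20_000)
        sheet = make_study(cfg, 2, tmp_path / "a")
        beds = sorted(p.name for p in (tmp_path / "a").glob("WT_*.bed"))
        assert len(beds) == 9  # 2 replicates x 4 plans + shared IgG-IgG
        assert len(sheet) == 9
        assert set(sheet["role"]) == {"k4_total", "k27_total", "k4k27",
                                      "k27k4", "igg_igg"}
        make_study(cfg, 2, tmp_path / "b")
        for name in beds:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_refuses_nonempty_outdir(self, tmp_path):
        cfg = small_config(seed=23, depth=5_000)
        make_study(cfg, 1, tmp_path / "x")
        with pytest.raises(FileExistsError):
            make_study(cfg, 1, tmp_path / "x")
        make_study(cfg, 1, tmp_path / "x", overwrite=True)

    def test_sheet_paths_load_and_seeds_derive_from_rule(self, tmp_path):
        cfg = small_config(seed=23, depth=5_000)
        sheet = make_study(cfg, 1, tmp_path / "y")
        for row in sheet.itertuples(index=False):
            assert row.seed == sample_seed(cfg.seed, row.sample_id)
            assert read_fragments(row.path).library_size > 0
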