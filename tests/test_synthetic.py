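"""Synthetic genome generator: determinism, geometry, kinetics, fragments."""

import math

import numpy as np
import pandas as pd
import pytest

from phasekin import synthetic
from phasekin.sinefit import SinePhaseParams, sine_eval
from phasekin.synthetic import (
    SimConfig,
    make_genome,
    simulate_fragments,
    simulate_timecourse,
    truth_rates,
    wt_params,
)


class TestMakeGenome:
    def test_small_genome_counts(self):
        cfg = SimConfig(n_genes=10, chrom_lengths=(50_000,),
                        mean_site_interval=256, seed=7)
        g = make_genome(cfg)
        assert len(g.genes) == 10
        n_chr1 = int((g.sites["chrom"] == "chr1").sum())
        assert n_chr1 == pytest.approx(195, rel=0.15)

    def test_mt_site_count_near_expectation(self):
        cfg = SimConfig(n_genes=10, chrom_lengths=(50_000,), seed=3)
        g = make_genome(cfg)
        n_mt = int((g.sites["region"] == "mt").sum())
        assert abs(n_mt - 335) / 335 < 0.2  # 85,800 / 256 ~ 335

    def test_seed_determinism(self):
        cfg = SimConfig(n_genes=15, chrom_lengths=(60_000,), seed=99)
        a, b = make_genome(cfg), make_genome(cfg)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_minus_strand_share(self, small_genome):
        share = (small_genome.genes["strand"] == "-").mean()
        assert share >= 0.4

    def test_genes_do_not_overlap(self, small_genome):
        g = small_genome.genes
        spans = sorted(
            (min(r.tss, r.end), max(r.tss, r.end)) for r in g.itertuples())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_every_site_has_one_region(self, small_genome):
        assert small_genome.sites["region"].notna().all()
        assert (small_genome.sites.loc[small_genome.sites["chrom"] == "chrM",
                                       "region"] == "mt").all()

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="slots"):
            make_genome(SimConfig(n_genes=100, chrom_lengths=(50_000,)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(timepoints=(60.0, 30.0))
        with pytest.raises(ValueError):
            SimConfig(noise="binomial", coverage=0)
        with pytest.raises(ValueError):
            SimConfig(mt_rate=-1.0)


class TestTruthRates:
    def test_flat_landscape(self, small_genome):
        p = SinePhaseParams(0.0, 0.0, 2 * math.pi / 165, -math.pi / 2, 0.0, 1.0)
        r = truth_rates(small_genome, params=p, mt_rate=0.01)
        genic = small_genome.sites["region"].isin(["genic", "gene_tail"])
        np.testing.assert_allclose(r[genic], 0.01)

    def test_trough_value_at_dyad(self, small_genome):
        p = SinePhaseParams(0.3, 0.0, 2 * math.pi / 165, -math.pi / 2, 0.0, 1.0)
        # rate at offset 0 must be mt_rate * (baseline - A)
        r = truth_rates(small_genome, params=p, mt_rate=0.01)
        sites = small_genome.sites
        at0 = (sites["offset"] == 0) & (sites["region"] == "genic")
        if at0.any():
            np.testing.assert_allclose(r[at0], 0.01 * 0.7)
        assert sine_eval(p, 0.0) == pytest.approx(0.7)

    def test_mt_and_ndr_rates(self, small_genome, small_rates):
        sites = small_genome.sites
        cfg = small_genome.config
        np.testing.assert_allclose(small_rates[sites["region"] == "mt"], cfg.mt_rate)
        np.testing.assert_allclose(small_rates[sites["region"] == "ndr"],
                                   cfg.mt_rate * cfg.ndr_rate_factor)

    def test_rates_positive_finite(self, small_rates):
        assert np.isfinite(small_rates).all()
        assert (small_rates > 0).all()

    def test_nonpositive_landscape_rejected(self, small_genome):
        bad = SinePhaseParams(2.0, 0.0, 2 * math.pi / 165, -math.pi / 2, 0.0, 1.0)
        with pytest.raises(ValueError, match="non-positive"):
            truth_rates(small_genome, params=bad)

    def test_tail_sites_take_window_edge_value(self, small_genome):
        p = wt_params()
        r = truth_rates(small_genome, params=p, mt_rate=0.01)
        tail = small_genome.sites["region"] == "gene_tail"
        assert tail.any()
        np.testing.assert_allclose(r[tail], 0.01 * sine_eval(p, 1000.0))


class TestTimecourse:
    def test_known_fraction(self):
        f = simulate_timecourse(np.array([0.5]), [2.0])
        assert f[0, 0] == pytest.approx(1 - math.exp(-1), abs=1e-12)
        assert f[0, 0] == pytest.approx(0.63212, abs=1e-5)

    def test_time_zero_is_zero(self):
        f = simulate_timecourse(np.array([0.3, 0.7]), [0.0, 10.0])
        np.testing.assert_allclose(f[:, 0], 0.0)

    def test_nonzero_intercept(self):
        f = simulate_timecourse(np.array([0.5]), [0.0], f0=0.2)
        assert f[0, 0] == pytest.approx(0.2)

    def test_monotone_in_time(self, small_timecourse):
        assert (np.diff(small_timecourse, axis=1) >= 0).all()

    def test_binomial_noise_near_truth(self):
        f = simulate_timecourse(np.array([0.01]), [120.0], noise="binomial",
                                coverage=10_000, seed=1)
        assert f[0, 0] == pytest.approx(1 - math.exp(-1.2), abs=0.02)

    def test_binomial_seed_determinism(self):
        k = np.full(50, 0.01)
        a = simulate_timecourse(k, [30.0, 60.0], noise="binomial", coverage=30, seed=8)
        b = simulate_timecourse(k, [30.0, 60.0], noise="binomial", coverage=30, seed=8)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def genome():
    return make_genome(SimConfig(n_genes=2, chrom_lengths=(8_000,),
                                 mt_length=3_000, seed=13))


class TestFragments:
    def test_unmethylated_full_length(self, genome):
        frac = np.zeros(len(genome.sites))
        frags = simulate_fragments(genome, frac, n_molecules=2, seed=1,
                                   fragment_min_length=0)
        # one full-length fragment per chromosome copy
        for chrom, clen in genome.chrom_lengths.items():
            sub = frags[frags["chrom"] == chrom]
            assert len(sub) == 2
            assert (sub["start"] == 0).all() and (sub["end"] == clen).all()

    def test_fully_methylated_cuts_at_every_site(self, genome):
        frac = np.ones(len(genome.sites))
        frags = simulate_fragments(genome, frac, n_molecules=1, seed=1,
                                   end_trim_prob=0.0, fragment_min_length=0,
                                   fragment_loss_prob=0.0)
        for chrom in genome.chrom_lengths:
            pos = genome.sites.loc[genome.sites["chrom"] == chrom, "pos"].to_numpy()
            cuts = set((pos + 2).tolist())
            sub = frags[frags["chrom"] == chrom]
            interior_ends = set(sub["end"]) - {genome.chrom_lengths[chrom]}
            assert interior_ends == cuts

    def test_seed_determinism(self, genome):
        frac = np.full(len(genome.sites), 0.4)
        a = simulate_fragments(genome, frac, 5, seed=3)
        b = simulate_fragments(genome, frac, 5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_short_fragments_lost(self, genome):
        frac = np.ones(len(genome.sites))
        full = simulate_fragments(genome, frac, 20, seed=2, end_trim_prob=0.0,
                                  fragment_min_length=0, fragment_loss_prob=0.0)
        lossy = simulate_fragments(genome, frac, 20, seed=2, end_trim_prob=0.0,
                                   fragment_min_length=200, fragment_loss_prob=1.0)
        assert (lossy["end"] - lossy["start"] >= 200).all()
        assert len(lossy) < len(full)
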