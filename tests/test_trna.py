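"""tRNA transcription-factor regions, class kinetics, and the aligned map."""

import numpy as np
import pandas as pd
import pytest

from phasekin import synthetic, trna
from phasekin.trna import (
    label_trna_sites,
    make_trna_regions,
    trna_aligned_map,
    trna_kinetics,
)


def trna_gene(gene_id="t1", chrom="chr1", strand="+", tss=500, length=72, introns=""):
    end = tss + length if strand == "+" else tss - length
    return {"gene_id": gene_id, "chrom": chrom, "strand": strand, "tss": tss,
            "plus1_dyad": tss, "end": end, "klass": "tRNA", "introns": introns}


class TestMakeRegions:
    def test_plus_strand_coordinates(self):
        out = make_trna_regions(pd.DataFrame([trna_gene()]))
        b = out[out["region"] == "tfiiib"].iloc[0]
        c = out[out["region"] == "tfiiic"].iloc[0]
        assert (b["start"], b["end"]) == (444, 488)
        assert (c["start"], c["end"]) == (498, 582)

    def test_minus_strand_mirrored(self):
        out = make_trna_regions(pd.DataFrame([trna_gene(strand="-", tss=572)]))
        b = out[out["region"] == "tfiiib"].iloc[0]
        c = out[out["region"] == "tfiiic"].iloc[0]
        # mirror of the plus-strand example around the TSS
        assert b["end"] - b["start"] == 44
        assert (b["start"], b["end"]) == (572 + 13, 572 + 57)
        assert (c["start"], c["end"]) == (572 - 81, 572 + 3)

    def test_intron_splits_tfiiic(self):
        out = make_trna_regions(
            pd.DataFrame([trna_gene(length=102, introns="530-560")]))
        c = out[out["region"] == "tfiiic"]
        assert len(c) == 2
        ivs = sorted(zip(c["start"], c["end"]))
        assert ivs == [(498, 530), (560, 612)]
        i = out[out["region"] == "trna_intron"].iloc[0]
        assert (i["start"], i["end"]) == (530, 560)

    def test_tfiiib_span_always_44(self, trna_genome):
        regions = make_trna_regions(
            trna_genome.genes[trna_genome.genes["klass"] == "tRNA"])
        b = regions[regions["region"] == "tfiiib"]
        assert ((b["end"] - b["start"]) == 44).all()

    def test_tfiiic_span_is_length_plus_12_minus_introns(self, trna_genome):
        genes = trna_genome.genes[trna_genome.genes["klass"] == "tRNA"]
        regions = make_trna_regions(genes)
        spans = regions[regions["region"] == "tfiiic"].groupby("gene_id").apply(
            lambda d: (d["end"] - d["start"]).sum(), include_groups=False)
        for row in genes.itertuples():
            glen = abs(row.end - row.tss)
            intron_len = sum(
                int(iv.split("-")[1]) - int(iv.split("-")[0])
                for iv in row.introns.split(";") if iv)
            assert spans[row.gene_id] == glen + 12 - intron_len

    def test_intron_outside_body_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_trna_regions(pd.DataFrame([trna_gene(introns="100-120")]))

    def test_tfiiib_tfiiic_disjoint(self, trna_genome):
        regions = make_trna_regions(
            trna_genome.genes[trna_genome.genes["klass"] == "tRNA"])
        for _, grp in regions.groupby("gene_id"):
            ivs = sorted(zip(grp["start"], grp["end"]))
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                assert a1 <= b0


class TestKinetics:
    def test_constructed_ratios(self):
        rates = np.array([1.0, 1.0, 1.5, 1.5, 2.0])
        labels = ["tfiiib", "tfiiib", "tfiiic", "tfiiic", "trna_intron"]
        out = trna_kinetics(rates, labels)
        assert out["ratio_tfiiic_tfiiib"] == pytest.approx(1.5)
        assert out["ratio_intron_tfiiib"] == pytest.approx(2.0)

    def test_equal_classes_unit_ratios(self):
        out = trna_kinetics(np.ones(6),
                            ["tfiiib", "tfiiic", "trna_intron"] * 2)
        assert out["ratio_tfiiic_tfiiib"] == pytest.approx(1.0)
        assert out["ratio_intron_tfiiib"] == pytest.approx(1.0)

    def test_generator_ratios_and_trajectory_agreement(self, trna_genome):
        """Per-site medians and median-trajectory fits agree on homogeneous
        synthetic classes, and ratios match the generating factors."""
        cfg = trna_genome.config
        rates = synthetic.truth_rates(trna_genome)
        tc = synthetic.simulate_timecourse(rates, cfg.timepoints)
        labels = trna_genome.sites["region"].to_numpy()
        norm = rates / cfg.mt_rate
        out = trna_kinetics(norm, labels, timecourse=tc, times=cfg.timepoints)
        b_f, c_f, i_f = cfg.trna_rate_factors
        assert out["ratio_tfiiic_tfiiib"] == pytest.approx(c_f / b_f, rel=1e-9)
        assert out["ratio_intron_tfiiib"] == pytest.approx(i_f / b_f, rel=1e-9)
        for klass, factor in zip(("tfiiib", "tfiiic", "trna_intron"),
                                 (b_f, c_f, i_f)):
            assert out["trajectory_rate"][klass] / cfg.mt_rate == pytest.approx(
                out["median_rate"][klass], rel=0.01)
            assert out["median_rate"][klass] == pytest.approx(factor, rel=1e-9)

    def test_empty_class_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = trna_kinetics(np.ones(2), ["tfiiib", "tfiiic"])
        assert np.isnan(out["ratio_intron_tfiiib"])


class TestAlignedMap:
    def make_sites(self, genes, value=1.2, step=4):
        rows = []
        for row in genes.itertuples():
            sign = 1 if row.strand == "+" else -1
            for off in range(-100, 250, step):
                rows.append((row.chrom, row.tss + sign * off))
        sites = pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates()
        sites = sites.sort_values(["chrom", "pos"], ignore_index=True)
        return sites, np.full(len(sites), value)

    def test_flat_rate_flat_map(self):
        genes = pd.DataFrame([trna_gene(gene_id=f"t{i}", tss=1000 + 2000 * i)
                              for i in range(3)])
        sites, rates = self.make_sites(genes, value=1.2, step=1)
        out = trna_aligned_map(rates, sites, genes, min_genes_per_offset=1)
        covered = out[out["n_genes"] > 0]
        np.testing.assert_allclose(covered["mean"], 1.2)
        np.testing.assert_allclose(covered["sd"], 0.0, atol=1e-6)

    def test_short_genes_mask_discontinuity(self):
        genes = pd.DataFrame([trna_gene(gene_id=f"t{i}", tss=1000 + 2000 * i)
                              for i in range(3)])  # all length 72
        sites, rates = self.make_sites(genes, step=1)
        out = trna_aligned_map(rates, sites, genes, min_genes_per_offset=1)
        zone = out[(out["offset"] >= 72) & (out["offset"] < 100)]
        assert (zone["n_genes"] == 0).all()
        assert zone["mean"].isna().all()

    def test_mean_matches_brute_force(self, rng):
        genes = pd.DataFrame(
            [trna_gene(gene_id=f"t{i}", tss=1000 + 2500 * i,
                       strand="+" if i % 2 else "-",
                       length=72 if i % 3 else 110)
             for i in range(6)])
        rows = []
        for row in genes.itertuples():
            sign = 1 if row.strand == "+" else -1
            for off in range(-100, 260, 3):
                rows.append((row.chrom, row.tss + sign * off))
        sites = pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates()
        sites = sites.sort_values(["chrom", "pos"], ignore_index=True)
        rates = rng.uniform(0.5, 2.0, len(sites))

        out = trna_aligned_map(rates, sites, genes, min_genes_per_offset=1)
        lookup = {(c, p): v for c, p, v in zip(sites["chrom"], sites["pos"], rates)}
        for off in (-50, 0, 40, 71, 100, 150):
            vals = []
            for row in genes.itertuples():
                glen = abs(row.end - row.tss)
                sign = 1 if row.strand == "+" else -1
                if 0 <= off < 100 and off >= glen:
                    continue
                gpos = row.tss + sign * (off if off < 100 else glen + off - 72)
                if (row.chrom, gpos) in lookup:
                    vals.append(lookup[(row.chrom, gpos)])
            got = out.loc[out["offset"] == off].iloc[0]
            if vals:
                assert got["mean"] == pytest.approx(np.mean(vals), rel=1e-12)
                assert got["n_genes"] == len(vals)

    def test_no_intronless_genes_rejected(self):
        genes = pd.DataFrame([trna_gene(length=102, introns="530-560")])
        with pytest.raises(ValueError):
            trna_aligned_map(np.array([1.0]),
                             pd.DataFrame({"chrom": ["chr1"], "pos": [500]}), genes)
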