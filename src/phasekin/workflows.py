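"""End-to-end synthetic round-trip workflows.

Each workflow generates a synthetic genome whose ground-truth phasing
landscape is built from a published descriptor set, simulates noise-free
first-order methylation time courses, and runs the full analysis chain
(rate estimation, internal-control normalization, dyad-aligned profile,
decaying-sine fit) so the fitted descriptors can be compared against the
generating ones.  They double as the reproducibility entry points for the
reported parameter sets.
"""

from __future__ import annotations

import numpy as np

from . import gene_rates, kinetics, phasing, synthetic
from .sinefit import FitReport, params_from_descriptors

__all__ = ["dam_roundtrip", "cg_roundtrip", "quintile_roundtrip",
           "DAM_WT_DESCRIPTORS", "CG_WT_DESCRIPTORS", "CG_QUINTILE_DESCRIPTORS"]

#: Wild-type adenine-methylation fit descriptors (replicate 1):
#: spacing bp, amplitude, slope per kb, decay per period, adjusted mean rate.
DAM_WT_DESCRIPTORS = (166.3, 0.39, -0.12, 0.86, 0.80)

#: Wild-type CpG-methylation fit descriptors (replicate 1).
CG_WT_DESCRIPTORS = (169.7, 0.52, -0.34, 0.78, 1.04)

#: CpG-methylation descriptors per rate quintile (replicate 1), Q1..Q5.
CG_QUINTILE_DESCRIPTORS = {
    1: (167.4, 0.68, -0.34, 0.80, 0.71),
    2: (168.8, 0.62, -0.37, 0.79, 0.88),
    3: (169.9, 0.54, -0.35, 0.79, 1.01),
    4: (171.8, 0.46, -0.28, 0.79, 1.15),
    5: (173.1, 0.33, -0.25, 0.73, 1.44),
}


def _chrom_length(n_genes: int, cfg_slot: int = 2_600) -> int:
    return n_genes * cfg_slot + 2 * 300 + cfg_slot


def dam_roundtrip(seed: int = 0, n_genes: int = 2_000,
                  descriptors=DAM_WT_DESCRIPTORS) -> FitReport:
    """GATC-site pipeline with mtDNA normalization.

    Genome of ``n_genes`` genes with sites every ~256 bp plus circular
    mtDNA; noise-free fractions at 30/60/120/240 min; per-site rate fits;
    normalization by the median mitochondrial rate; genome-wide sine fit.
    """
    params = params_from_descriptors(*descriptors)
    cfg = synthetic.SimConfig(
        n_genes=n_genes, chrom_lengths=(_chrom_length(n_genes),),
        seed=seed, truth_params=params,
    )
    genome = synthetic.make_genome(cfg)
    rates = synthetic.truth_rates(genome)
    frac = synthetic.simulate_timecourse(rates, cfg.timepoints)
    fits = kinetics.fit_first_order(cfg.timepoints, frac)
    ref = kinetics.mtdna_reference(fits, genome.sites)
    norm = kinetics.normalize(fits["k_app"].to_numpy(), ref)
    report, _ = phasing.phase_fit(norm, genome.sites, genome.genes)
    return report


def cg_roundtrip(seed: int = 0, n_genes: int = 2_000,
                 descriptors=CG_WT_DESCRIPTORS) -> FitReport:
    """CG-site pipeline with genome-median normalization.

    As :func:`dam_roundtrip` but with CG sites every ~16 bp, the 2-micron
    plasmid included, and the reference taken from the genome-wide median
    fraction trajectory.
    """
    params = params_from_descriptors(*descriptors)
    cfg = synthetic.cg_config(
        n_genes=n_genes, chrom_lengths=(_chrom_length(n_genes),),
        seed=seed, truth_params=params,
    )
    genome = synthetic.make_genome(cfg)
    rates = synthetic.truth_rates(genome)
    frac = synthetic.simulate_timecourse(rates, cfg.timepoints)
    fits = kinetics.fit_first_order(cfg.timepoints, frac)
    ref = kinetics.genome_median_reference(cfg.timepoints, frac)
    norm = kinetics.normalize(fits["k_app"].to_numpy(), ref)
    report, _ = phasing.phase_fit(norm, genome.sites, genome.genes)
    return report


def quintile_roundtrip(seed: int = 0, n_genes: int = 2_000,
                       descriptors=None) -> list[FitReport]:
    """Heterogeneous CG genome: five gene populations, ranked and refit.

    One fifth of genes is generated from each per-quintile descriptor row;
    the pipeline ranks genes by bias-corrected mean rate, splits them into
    quintiles and refits the phasing model per quintile.  Returns the five
    fit reports, Q1 (slowest) to Q5 (fastest).
    """
    descriptors = descriptors or CG_QUINTILE_DESCRIPTORS
    qparams = {q: params_from_descriptors(*row) for q, row in descriptors.items()}
    cfg = synthetic.cg_config(
        n_genes=n_genes, chrom_lengths=(_chrom_length(n_genes),), seed=seed,
    )
    genome = synthetic.make_genome(cfg)
    gene_params = {row.gene_id: qparams[(i % 5) + 1]
                   for i, row in enumerate(genome.genes.itertuples(index=False))}
    rates = synthetic.truth_rates(genome, gene_params=gene_params)
    frac = synthetic.simulate_timecourse(rates, cfg.timepoints)
    fits = kinetics.fit_first_order(cfg.timepoints, frac)
    ref = kinetics.genome_median_reference(cfg.timepoints, frac)
    norm = kinetics.normalize(fits["k_app"].to_numpy(), ref)
    pop, _ = phasing.phase_fit(norm, genome.sites, genome.genes)
    records = gene_rates.gene_unbiased_rates(
        norm, genome.sites, genome.genes, pop.params, pop.derived.adj_mean_rate)
    records = gene_rates.assign_quintiles(records)
    return gene_rates.quintile_phase_fits(records, norm, genome.sites, genome.genes)
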