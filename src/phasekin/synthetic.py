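"""Synthetic genomes, rate landscapes, time courses and fragments.

Every downstream stage of the pipeline is exercised against data generated
here with known ground truth: a toy genome of non-overlapping genes on
both strands, each carrying a +1 nucleosome dyad; motif sites placed at a
jittered mean interval; a circular mitochondrial genome whose sites share
one uniform rate (the non-nucleosomal internal control); optional tRNA
genes with TFIIIB / TFIIIC / intron subregions; per-site true methylation
rates built from a decaying sine phasing landscape; first-order
methylation time courses with optional binomial sampling noise; and
restriction-style fragments whose ends encode per-site methylation.

Defaults reproduce the study conditions: GATC sites every ~256 bp (CpG
mode: ~16 bp), an 85.8 kb circular mtDNA, induction timepoints 30, 60,
120 and 240 min, and a wild-type phasing landscape (166.3 bp spacing,
amplitude 0.39, decay 0.86 per period, slope −0.12 per kb, adjusted mean
rate 0.80 relative to the control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sinefit import DEFAULT_FIT_RANGE, SinePhaseParams, params_from_descriptors, sine_eval

__all__ = ["SimConfig", "SyntheticGenome", "make_genome", "truth_rates",
           "simulate_timecourse", "simulate_fragments", "wt_params"]


def wt_params() -> SinePhaseParams:
    """Wild-type adenine-methylation phasing landscape (replicate 1)."""
    return params_from_descriptors(
        spacing_bp=166.3, amplitude=0.39, slope_per_kb=-0.12,
        decay_per_period=0.86, adj_mean_rate=0.80,
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Geometry: genes are laid out in fixed, non-overlapping slots of
    ``gene_slot`` bp so that no site within one gene's fitting window
    [-50, +1000] can also fall in another's.  ``mt_length`` is circular.
    ``coverage`` is the mean number of molecules observing a site per
    timepoint (binomial noise mode).  ``ndr_rate_factor`` is the rate
    multiplier for promoter nucleosome-depleted regions relative to the
    control; ``background_factor`` is the multiplier for sites outside any
    modelled feature (default 1: typical chromatin methylates at the
    reference rate).
    """

    n_genes: int = 200
    chrom_lengths: tuple[int, ...] = (600_000,)
    mt_length: int = 85_800
    plasmid_included: bool = False
    plasmid_length: int = 6_318
    motif: str = "GATC"
    mean_site_interval: int = 256
    timepoints: tuple[float, ...] = (30.0, 60.0, 120.0, 240.0)
    coverage: int = 100
    noise: str = "none"
    seed: int = 0
    truth_params: SinePhaseParams = field(default_factory=wt_params)
    mt_rate: float = 0.005
    ndr_rate_factor: float = 1.5
    background_factor: float = 1.0
    fragment_min_length: int = 200
    fragment_loss_prob: float = 0.5
    end_trim_prob: float = 0.1
    f0: float = 0.0
    n_trna: int = 0
    trna_rate_factors: tuple[float, float, float] = (1.3, 1.95, 2.6)  # TFIIIB, TFIIIC, intron
    gene_slot: int = 2_600
    ndr_window: tuple[int, int] = (-180, -80)  # dyad-relative promoter NDR

    def __post_init__(self):
        if self.n_genes < 1 or self.mt_length <= 0 or self.mean_site_interval <= 0:
            raise ValueError("lengths, intervals and counts must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be >= 0 and strictly increasing")
        if self.noise not in ("none", "binomial"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        if self.noise == "binomial" and self.coverage < 1:
            raise ValueError("binomial noise requires coverage >= 1")
        if self.motif not in ("GATC", "CG"):
            raise ValueError(f"unsupported motif {self.motif!r}")
        if self.mt_rate <= 0:
            raise ValueError("mt_rate must be positive")
        if self.ndr_rate_factor < 1:
            raise ValueError("ndr_rate_factor must be >= 1")
        if not (0 <= self.fragment_loss_prob <= 1 and 0 <= self.end_trim_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.n_trna < 0 or self.n_trna >= self.n_genes:
            raise ValueError("n_trna must be in [0, n_genes)")


@dataclass
class SyntheticGenome:
    """Genome annotation plus site catalog with ground-truth region labels."""

    config: SimConfig
    genes: pd.DataFrame  # gene_id chrom strand tss plus1_dyad end klass introns
    sites: pd.DataFrame  # chrom pos region gene_id offset
    chrom_lengths: dict[str, int]
    circular: frozenset[str]

    @property
    def truth_rates_(self) -> np.ndarray:
        if "truth_rate" not in self.sites.columns:
            raise AttributeError("truth rates not assigned yet; call truth_rates()")
        return self.sites["truth_rate"].to_numpy()


# gene geometry inside a slot, dyad-relative (gene orientation)
_TSS_TO_DYAD = 60         # +1 dyad sits ~60 bp downstream of the TSS
_GENE_LEN = 1_160         # coding gene length used for the toy annotation
_TRNA_LEN = 72            # canonical tRNA gene length
_TRNA_LONG_LEN = 102      # intron-containing tRNA gene length
_TRNA_INTRON = (38, 58)   # gene-oriented intron interval of long tRNAs


def _place_sites(rng: np.random.Generator, length: int, interval: int) -> np.ndarray:
    """Jittered site positions at a mean spacing of ``interval`` bp."""
    n = max(int(round(length / interval)), 1)
    base = (np.arange(n) + 0.5) * (length / n)
    jitter = rng.integers(-interval // 3, interval // 3 + 1, size=n)
    pos = np.unique(np.clip(np.round(base).astype(np.int64) + jitter, 0, length - 4))
    return pos


def make_genome(config: SimConfig) -> SyntheticGenome:
    """Lay out genes and motif sites; label every site with one region.

    Region labels: ``ndr`` (promoter nucleosome-depleted region), ``genic``
    (dyad-relative offsets -50..+1000), ``flank`` (inside a gene slot but
    outside NDR and fit window), ``intergenic``, ``mt``, ``plasmid``,
    ``tfiiib`` / ``tfiiic`` / ``trna_intron`` / ``trna_flank`` for tRNA
    slots.  Deterministic for a given config (seeded).
    """
    rng = np.random.default_rng(config.seed)
    margin = 300
    slots = []  # (chrom, slot_start)
    for ci, clen in enumerate(config.chrom_lengths):
        chrom = f"chr{ci + 1}"
        n_slots = (clen - 2 * margin) // config.gene_slot
        for si in range(int(n_slots)):
            slots.append((chrom, margin + si * config.gene_slot))
    if len(slots) < config.n_genes:
        raise ValueError(
            f"chromosomes too short: {len(slots)} gene slots of {config.gene_slot} bp "
            f"available for {config.n_genes} genes"
        )
    slots = slots[: config.n_genes]

    # exactly balanced strands, seeded arrangement (>= 40% minus guaranteed)
    strands = np.array(["+", "-"])[rng.permutation(
        np.arange(config.n_genes) % 2)]
    # tRNA genes: a seeded subset of slots; every third one carries an intron
    trna_idx = set(rng.choice(config.n_genes, size=config.n_trna, replace=False).tolist()) \
        if config.n_trna else set()

    gene_rows = []
    for gi, ((chrom, start), strand) in enumerate(zip(slots, strands)):
        center = start + config.gene_slot // 2
        is_trna = gi in trna_idx
        if is_trna:
            glen = _TRNA_LONG_LEN if (gi % 3 == 0) else _TRNA_LEN
            if strand == "+":
                tss = center
                end = tss + glen
                dyad = tss
            else:
                tss = center
                end = tss - glen
                dyad = tss
            introns = []
            if glen == _TRNA_LONG_LEN:
                a, b = _TRNA_INTRON
                if strand == "+":
                    introns = [(tss + a, tss + b)]
                else:
                    introns = [(tss - b + 1, tss - a + 1)]
            klass = "tRNA"
        else:
            if strand == "+":
                dyad = center
                tss = dyad - _TSS_TO_DYAD
                end = tss + _GENE_LEN
            else:
                dyad = center
                tss = dyad + _TSS_TO_DYAD
                end = tss - _GENE_LEN
            introns = []
            klass = "coding"
        gene_rows.append(
            {"gene_id": f"g{gi:05d}", "chrom": chrom, "strand": strand, "tss": tss,
             "plus1_dyad": dyad, "end": end, "klass": klass,
             "introns": ";".join(f"{a}-{b}" for a, b in introns)}
        )
    genes = pd.DataFrame(gene_rows)

    chrom_lengths = {f"chr{ci + 1}": int(l) for ci, l in enumerate(config.chrom_lengths)}
    chrom_lengths["chrM"] = config.mt_length
    circular = frozenset({"chrM"})
    if config.plasmid_included:
        chrom_lengths["plasmid"] = config.plasmid_length
        circular = frozenset({"chrM", "plasmid"})

    site_frames = []
    for chrom, clen in chrom_lengths.items():
        pos = _place_sites(rng, clen, config.mean_site_interval)
        site_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(site_frames, ignore_index=True)

    sites["region"] = "intergenic"
    sites["gene_id"] = ""
    sites["offset"] = np.nan
    sites.loc[sites["chrom"] == "chrM", "region"] = "mt"
    if config.plasmid_included:
        sites.loc[sites["chrom"] == "plasmid", "region"] = "plasmid"

    fit_lo, fit_hi = DEFAULT_FIT_RANGE
    ndr_lo, ndr_hi = config.ndr_window
    pos_by_chrom = {c: grp for c, grp in sites.groupby("chrom", sort=False)}
    region = sites["region"].to_numpy(object)
    gene_id = sites["gene_id"].to_numpy(object)
    offset_col = sites["offset"].to_numpy()

    for row in genes.itertuples(index=False):
        grp = pos_by_chrom[row.chrom]
        all_pos = grp["pos"].to_numpy()
        all_idx = grp.index.to_numpy()
        half = config.gene_slot // 2
        a = np.searchsorted(all_pos, row.plus1_dyad - half, side="left")
        b = np.searchsorted(all_pos, row.plus1_dyad + half, side="right")
        pos = all_pos[a:b]
        idx = all_idx[a:b]
        sign = 1 if row.strand == "+" else -1
        off = sign * (pos - row.plus1_dyad)
        in_slot = np.abs(pos - row.plus1_dyad) <= half
        if row.klass == "tRNA":
            toff = sign * (pos - row.tss)  # gene-oriented 0-based offset from TSS
            glen = abs(row.end - row.tss)
            lab = np.where(
                (toff >= -56) & (toff <= -13), "tfiiib",
                np.where((toff >= -2) & (toff <= glen + 9), "tfiiic", "trna_flank"),
            )
            if row.introns:
                for iv in row.introns.split(";"):
                    a, b = (int(v) for v in iv.split("-"))
                    inside = (pos >= a) & (pos < b)
                    lab = np.where(inside, "trna_intron", lab)
            sel = in_slot
            region[idx[sel]] = lab[sel]
        else:
            body_hi = _GENE_LEN - _TSS_TO_DYAD  # dyad-relative gene end
            lab = np.where(
                (off >= ndr_lo) & (off <= ndr_hi), "ndr",
                np.where(
                    (off >= fit_lo) & (off <= fit_hi), "genic",
                    np.where((off > fit_hi) & (off <= body_hi), "gene_tail", "flank"),
                ),
            )
            sel = in_slot
            region[idx[sel]] = lab[sel]
        gene_id[idx[sel]] = row.gene_id
        offset_col[idx[sel]] = off[sel]

    sites["region"] = region
    sites["gene_id"] = gene_id
    sites["offset"] = offset_col
    sites = sites.sort_values(["chrom", "pos"], ignore_index=True)

    return SyntheticGenome(config=config, genes=genes, sites=sites,
                           chrom_lengths=chrom_lengths, circular=circular)


RATE_FLOOR_FACTOR = 1e-4  # numerical guard relative to the control rate


def truth_rates(
    genome: SyntheticGenome,
    params: SinePhaseParams | None = None,
    mt_rate: float | None = None,
    ndr_rate_factor: float | None = None,
    gene_params: dict[str, SinePhaseParams] | None = None,
) -> np.ndarray:
    """Assign every site its true per-minute methylation rate.

    Genic sites (offset in the fit window) take ``mt_rate`` times the
    phasing-landscape value at their dyad-relative offset; offsets past
    +1000 take the window-edge value (the model is not extrapolated).
    Promoter NDR sites take ``mt_rate * ndr_rate_factor``; mitochondrial
    sites take ``mt_rate`` exactly; remaining background takes
    ``mt_rate * background_factor``.  tRNA subregions take the configured
    TFIIIB / TFIIIC / intron factors.  ``gene_params`` overrides the
    landscape per gene (heterogeneous-genome scenarios).

    Raises a configuration error if any generating landscape is
    non-positive anywhere on the integer fit window.
    """
    cfg = genome.config
    params = params if params is not None else cfg.truth_params
    mt_rate = mt_rate if mt_rate is not None else cfg.mt_rate
    ndr_f = ndr_rate_factor if ndr_rate_factor is not None else cfg.ndr_rate_factor

    lo, hi = DEFAULT_FIT_RANGE
    grid = np.arange(lo, hi + 1, dtype=float)
    all_params = [params] + (list(gene_params.values()) if gene_params else [])
    for p in all_params:
        if float(np.min(sine_eval(p, grid))) <= 0:
            raise ValueError("phasing landscape is non-positive inside the fit window")

    sites = genome.sites
    region = sites["region"].to_numpy()
    off = sites["offset"].to_numpy()
    rate = np.full(len(sites), cfg.background_factor * mt_rate)

    rate[region == "mt"] = mt_rate
    rate[region == "ndr"] = ndr_f * mt_rate
    b_f, c_f, i_f = cfg.trna_rate_factors
    rate[region == "tfiiib"] = b_f * mt_rate
    rate[region == "tfiiic"] = c_f * mt_rate
    rate[region == "trna_intron"] = i_f * mt_rate

    # gene-body sites past the fit window take the window-edge value (the
    # landscape is never extrapolated); np.clip below handles both labels
    genic = (region == "genic") | (region == "gene_tail")
    if gene_params:
        gid = sites["gene_id"].to_numpy()
        for g, p in gene_params.items():
            m = genic & (gid == g)
            if m.any():
                rate[m] = mt_rate * sine_eval(p, np.clip(off[m], lo, hi))
        rest = genic & ~np.isin(gid, list(gene_params))
        if rest.any():
            rate[rest] = mt_rate * sine_eval(params, np.clip(off[rest], lo, hi))
    else:
        rate[genic] = mt_rate * sine_eval(params, np.clip(off[genic], lo, hi))

    rate = np.maximum(rate, RATE_FLOOR_FACTOR * mt_rate)
    genome.sites["truth_rate"] = rate
    return rate


def simulate_timecourse(
    rates,
    timepoints,
    noise: str = "none",
    coverage: int = 100,
    seed: int = 0,
    f0: float = 0.0,
) -> np.ndarray:
    """First-order methylation time courses per site.

    Noise-free: fraction(site, t) = 1 − (1 − f0)·exp(−k t).  Binomial
    noise: the observed fraction is Binomial(coverage, true)/coverage,
    seeded.  Returns a (n_sites, n_timepoints) array.
    """
    k = np.asarray(rates, dtype=float)[:, None]
    t = np.asarray(timepoints, dtype=float)[None, :]
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    if not (0 <= f0 < 1):
        raise ValueError("f0 must be in [0, 1)")
    true = 1.0 - (1.0 - f0) * np.exp(-k * t)
    if noise == "none":
        return true
    if noise == "binomial":
        rng = np.random.default_rng(seed)
        return rng.binomial(coverage, true) / coverage
    raise ValueError(f"unknown noise mode {noise!r}")


def simulate_fragments(
    genome: SyntheticGenome,
    fractions_at_t,
    n_molecules: int,
    seed: int = 0,
    end_trim_prob: float | None = None,
    fragment_min_length: int | None = None,
    fragment_loss_prob: float | None = None,
) -> pd.DataFrame:
    """Restriction-style fragments encoding per-site methylation.

    Per simulated genome copy, each site is methylated independently with
    its current fraction; methylated sites are cut between the A and the T
    (coordinate pos+2).  A configurable share of cut ends is trimmed by
    one base (losing the terminal A of the left fragment or T of the
    right).  Fragments shorter than the minimum length are dropped with
    the configured loss probability (short restriction fragments are lost
    during library preparation).  Circular sequences are linearized at the
    origin for fragment emission.

    Returns a BED-like DataFrame (chrom, start, end), 0-based half-open.
    """
    cfg = genome.config
    trim = cfg.end_trim_prob if end_trim_prob is None else end_trim_prob
    min_len = cfg.fragment_min_length if fragment_min_length is None else fragment_min_length
    loss = cfg.fragment_loss_prob if fragment_loss_prob is None else fragment_loss_prob
    rng = np.random.default_rng(seed)

    sites = genome.sites
    frac = np.asarray(fractions_at_t, dtype=float)
    if frac.shape[0] != len(sites):
        raise ValueError("one fraction per site required")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fractions must be probabilities")

    rows_chrom, rows_start, rows_end = [], [], []
    for chrom, clen in genome.chrom_lengths.items():
        m = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[m, "pos"].to_numpy()
        p = frac[m]
        cut_coords = pos + 2
        for _ in range(int(n_molecules)):
            meth = rng.random(pos.size) < p
            cuts = cut_coords[meth]
            bounds = np.concatenate(([0], cuts, [clen]))
            starts = bounds[:-1].copy()
            ends = bounds[1:].copy()
            # trim interior cut ends by one base, independently per end
            if trim > 0 and cuts.size:
                lose_a = rng.random(cuts.size) < trim  # left fragment loses terminal A
                lose_t = rng.random(cuts.size) < trim  # right fragment loses leading T
                ends[:-1][lose_a] -= 1
                starts[1:][lose_t] += 1
            keep = ends > starts
            if min_len > 0:
                short = keep & (ends - starts < min_len)
                drop = short & (rng.random(starts.size) < loss)
                keep &= ~drop
            rows_chrom.extend([chrom] * int(keep.sum()))
            rows_start.extend(starts[keep].tolist())
            rows_end.extend(ends[keep].tolist())

    return pd.DataFrame({"chrom": rows_chrom,
                         "start": np.asarray(rows_start, dtype=np.int64),
                         "end": np.asarray(rows_end, dtype=np.int64)})


def cg_config(**overrides) -> SimConfig:
    """Convenience: CpG-methylation study conditions (dense CG sites,
    genome-median normalization downstream)."""
    base = dict(motif="CG", mean_site_interval=16, plasmid_included=True)
    base.update(overrides)
    return SimConfig(**base)
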