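"""tRNA gene transcription-factor footprint regions and their kinetics.

RNA polymerase III transcription factors protect defined windows around
tRNA genes: TFIIIB binds the promoter at positions −56 to −13 relative to
the transcription start (+1 = first transcribed base, 1-based), and
TFIIIC binds from −2 to 10 bp past the gene end, excluding the intron
when present (introns loop out of the complex and are only weakly
protected).  Comparing methylation kinetics between these regions reports
on factor residence dynamics in vivo.

Coordinates are converted to 0-based half-open genomic intervals;
minus-strand genes are mirrored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import kinetics

__all__ = ["make_trna_regions", "label_trna_sites", "trna_kinetics",
           "trna_aligned_map", "TFIIIB_REL", "TFIIIC_UP_REL", "TFIIIC_DOWN_EXT"]

#: TFIIIB window, 1-based positions relative to the TSS (inclusive).
TFIIIB_REL = (-56, -13)
#: TFIIIC upstream bound (1-based relative) and downstream extension past
#: the gene end, bp.
TFIIIC_UP_REL = -2
TFIIIC_DOWN_EXT = 10

#: Canonical tRNA gene length used as the alignment frame, bp.
NOMINAL_TRNA_LEN = 72


def _oriented_to_genomic(tss: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map a gene-oriented 0-based half-open interval [a, b) (offset 0 =
    first transcribed base) to genomic coordinates."""
    if strand == "+":
        return tss + a, tss + b
    return tss - b + 1, tss - a + 1


def _gene_len(row) -> int:
    return abs(row.end - row.tss)


def _parse_introns(field: str) -> list[tuple[int, int]]:
    if not field or (isinstance(field, float) and np.isnan(field)):
        return []
    out = []
    for iv in str(field).split(";"):
        a, b = (int(v) for v in iv.split("-"))
        out.append((a, b))
    return out


def _subtract(intervals: list[tuple[int, int]], cuts: list[tuple[int, int]]):
    """Set-subtract ``cuts`` from ``intervals`` (0-based half-open)."""
    out = list(intervals)
    for ca, cb in cuts:
        nxt = []
        for a, b in out:
            if cb <= a or ca >= b:
                nxt.append((a, b))
                continue
            if a < ca:
                nxt.append((a, ca))
            if cb < b:
                nxt.append((cb, b))
        out = nxt
    return out


def make_trna_regions(genes: pd.DataFrame) -> pd.DataFrame:
    """Per-tRNA-gene TFIIIB / TFIIIC / intron intervals.

    Input genes must be tRNA-class records with tss, end (gene-oriented
    exclusive), strand and an optional semicolon-separated genomic intron
    field.  Output is a BED-like frame (chrom, start, end, gene_id,
    region) with region in {tfiiib, tfiiic, trna_intron}; the TFIIIC
    footprint is split around introns.
    """
    rows = []
    for row in genes.itertuples(index=False):
        if getattr(row, "klass", "tRNA") != "tRNA":
            raise ValueError(f"{row.gene_id} is not a tRNA gene")
        glen = _gene_len(row)
        introns = _parse_introns(getattr(row, "introns", ""))
        for a, b in introns:
            g_lo, g_hi = (row.tss, row.tss + glen) if row.strand == "+" else \
                         (row.tss - glen + 1, row.tss + 1)
            if not (g_lo <= a < b <= g_hi):
                raise ValueError(f"{row.gene_id}: intron [{a},{b}) outside gene body")

        # 1-based relative −56..−13 -> gene-oriented 0-based [−56, −12)
        b_start, b_end = _oriented_to_genomic(
            row.tss, row.strand, TFIIIB_REL[0], TFIIIB_REL[1] + 1)
        rows.append((row.chrom, b_start, b_end, row.gene_id, "tfiiib"))

        c_start, c_end = _oriented_to_genomic(
            row.tss, row.strand, TFIIIC_UP_REL, glen + TFIIIC_DOWN_EXT)
        for a, b in _subtract([(c_start, c_end)], introns):
            rows.append((row.chrom, a, b, row.gene_id, "tfiiic"))
        for a, b in introns:
            rows.append((row.chrom, a, b, row.gene_id, "trna_intron"))

    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "region"])
    return out.sort_values(["chrom", "start"], ignore_index=True)


def label_trna_sites(sites: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Region label per site ('' when a site is in no tRNA region)."""
    labels = pd.Series("", index=sites.index, dtype=object)
    for chrom, rgrp in regions.groupby("chrom", sort=False):
        m = sites["chrom"] == chrom
        pos = sites.loc[m, "pos"].to_numpy()
        lab = np.full(pos.size, "", dtype=object)
        for r in rgrp.itertuples(index=False):
            lab[(pos >= r.start) & (pos < r.end)] = r.region
        labels.loc[m] = lab
    return labels


def trna_kinetics(
    norm_rates,
    labels,
    timecourse=None,
    times=None,
) -> dict:
    """Per-class rate summaries and the TFIIIC/TFIIIB, intron/TFIIIB ratios.

    ``labels`` holds tfiiib / tfiiic / trna_intron per site (others
    ignored).  When a time course is supplied, per-class median fraction
    trajectories and their first-order rate fits are also returned.
    Empty classes yield NaN medians and flagged, undefined ratios.
    """
    rates = np.asarray(norm_rates, dtype=float)
    labels = np.asarray(labels)
    med = {}
    for klass in ("tfiiib", "tfiiic", "trna_intron"):
        vals = rates[(labels == klass) & np.isfinite(rates)]
        if vals.size == 0:
            warnings.warn(f"no sites in tRNA class {klass!r}", RuntimeWarning, stacklevel=2)
            med[klass] = float("nan")
        else:
            med[klass] = float(np.median(vals))
    out = {
        "median_rate": med,
        "ratio_tfiiic_tfiiib": med["tfiiic"] / med["tfiiib"],
        "ratio_intron_tfiiib": med["trna_intron"] / med["tfiiib"],
    }
    if timecourse is not None and times is not None:
        tc = np.asarray(timecourse, dtype=float)
        traj, traj_k = {}, {}
        for klass in ("tfiiib", "tfiiic", "trna_intron"):
            m = labels == klass
            if not m.any():
                continue
            traj[klass] = np.nanmedian(tc[m], axis=0)
            traj_k[klass] = kinetics.fit_single_trajectory(times, traj[klass])
        out["median_trajectory"] = traj
        out["trajectory_rate"] = traj_k
    return out


def trna_aligned_map(
    norm_rates,
    sites: pd.DataFrame,
    trna_genes: pd.DataFrame,
    upstream: int = 100,
    downstream: int = 100,
    min_genes_per_offset: int = 10,
    nominal_len: int = NOMINAL_TRNA_LEN,
) -> pd.DataFrame:
    """TSS-aligned mean ± SD rate map over intronless tRNA genes.

    Offsets are gene-oriented bp from the TSS (offset 0 = first
    transcribed base).  Offsets below ``nominal_len + downstream_gap``
    come from the TSS frame; because genes longer than the nominal length
    are rare, offsets in [nominal_len, 100) are only covered by long genes
    and are masked when fewer than ``min_genes_per_offset`` genes
    contribute.  Offsets >= 100 are computed in a downstream frame
    anchored at each gene's own end (genomic position
    end + offset − nominal_len), so the region downstream of the
    terminator lines up across genes of different lengths.
    """
    rates = np.asarray(norm_rates, dtype=float)
    genes = trna_genes[trna_genes["introns"].fillna("") == ""] \
        if "introns" in trna_genes.columns else trna_genes
    if genes.empty:
        raise ValueError("no intronless tRNA genes")

    pos_by_chrom = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        order = np.argsort(p, kind="stable")
        pos_by_chrom[chrom] = (p[order], grp.index.to_numpy()[order])

    offsets = np.arange(-upstream, 100 + downstream)
    sums = np.zeros(offsets.size)
    sqs = np.zeros(offsets.size)
    ns = np.zeros(offsets.size, dtype=np.int64)

    for row in genes.itertuples(index=False):
        if row.chrom not in pos_by_chrom:
            continue
        pos, idx = pos_by_chrom[row.chrom]
        glen = _gene_len(row)
        sign = 1 if row.strand == "+" else -1
        for j, off in enumerate(offsets):
            if off < 100:
                if 0 <= off < 100 and off >= glen:
                    continue  # discontinuity zone: this gene is too short
                gpos = row.tss + sign * off  # TSS frame
            else:
                # downstream frame anchored at the gene's own end
                gpos = row.tss + sign * (glen + off - nominal_len)
            k = np.searchsorted(pos, gpos)
            if k < pos.size and pos[k] == gpos:
                v = rates[idx[k]]
                if np.isfinite(v):
                    sums[j] += v
                    sqs[j] += v * v
                    ns[j] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        var = np.where(ns > 0, sqs / np.maximum(ns, 1) - mean**2, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0))

    mask_zone = (offsets >= nominal_len) & (offsets < 100)
    masked = mask_zone & (ns < min_genes_per_offset)
    mean[masked] = np.nan
    sd[masked] = np.nan
    return pd.DataFrame({"offset": offsets, "mean": mean, "sd": sd, "n_genes": ns})
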