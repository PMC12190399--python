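"""Fragment-end counting for restriction-assisted methylation quantification.

DpnI cuts GATC sites that are adenine-methylated on both strands, leaving
blunt ends between the A and the T (some molecules lose the terminal A or
T).  After sequencing, the methylated fraction of a site is inferred from
fragment ends: molecules whose fragment ends on the G or the A of a GATC
(left half-site), or begins with the T or the C (right half-site), were
cut and hence methylated; molecules whose fragments span the site were
not.  Each half-site ratio is (qualifying ends) / (protection-side
coverage of the outer base).  Half-sites whose nearest neighboring site is
closer than a minimum distance are discarded, because the short fragments
they would produce are lost during library preparation.

Coordinates are 0-based half-open throughout.  For a GATC with first base
at ``pos``: G = pos, A = pos+1, T = pos+2, C = pos+3; the blunt cut falls
at coordinate pos+2.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "find_motif_sites",
    "count_half_sites",
    "quantify_fractions",
    "MIN_NEIGHBOR_BP",
]

#: Half-sites with a neighboring site closer than this many bp are dropped.
MIN_NEIGHBOR_BP = 200

_MOTIFS = {"GATC": 4, "CG": 2}


def find_motif_sites(sequences: dict[str, str], motif: str = "GATC") -> pd.DataFrame:
    """Locate all exact motif matches on the forward strand.

    GATC and CG are palindromic, so forward-strand matches cover both
    strands; fractions are strand-combined at the site level.

    Parameters
    ----------
    sequences
        Mapping chrom name -> uppercase nucleotide string.  Characters
        outside ACGT interrupt matches and are skipped with a warning.

    Returns
    -------
    DataFrame (chrom, pos) sorted by (chrom, pos); ``pos`` is the 0-based
    position of the motif's first base.
    """
    if motif not in _MOTIFS:
        raise ValueError(f"unsupported motif {motif!r}; expected one of {sorted(_MOTIFS)}")
    pat = re.compile(f"(?={motif})")
    rows = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        if re.search(r"[^ACGT]", seq):
            warnings.warn(f"{chrom}: non-ACGT characters present; they never match",
                          RuntimeWarning, stacklevel=2)
        for m in pat.finditer(seq):
            rows.append((chrom, m.start()))
    return pd.DataFrame(rows, columns=["chrom", "pos"]).astype({"pos": np.int64})


def _neighbor_distances(pos: np.ndarray, chrom_len: int | None, circular: bool):
    """Distance to the adjacent site on each side; open ends get +inf,
    circular sequences wrap modularly."""
    n = pos.size
    left = np.full(n, np.inf)
    right = np.full(n, np.inf)
    if n >= 2:
        d = np.diff(pos).astype(float)
        left[1:] = d
        right[:-1] = d
    if circular:
        if chrom_len is None:
            raise ValueError("circular chromosome requires a length")
        if n >= 2:
            wrap = float(pos[0] + chrom_len - pos[-1])
            left[0] = wrap
            right[-1] = wrap
        elif n == 1:
            left[0] = right[0] = float(chrom_len)
    return left, right


def count_half_sites(
    fragments: pd.DataFrame,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    circular: set[str] | frozenset[str] = frozenset(),
    motif: str = "GATC",
) -> pd.DataFrame:
    """Per-site fragment-end and coverage counts.

    For a GATC with bases g, a, t, c (g = pos):

    * ``ends_at_G``   fragments with end coordinate g+1 (terminal A lost)
    * ``ends_at_A``   fragments with end coordinate g+2 (blunt cut)
    * ``starts_at_T`` fragments with start coordinate g+2 (blunt cut)
    * ``starts_at_C`` fragments with start coordinate g+3 (terminal T lost)
    * ``cov_G``       fragments covering g and extending past the cut
                      (start <= g, end >= g+2); a fragment that ends on the
                      G does not count — the molecule was cut there and no
                      longer reports protection of that base
    * ``cov_C``       mirror image (start <= g+2, end >= g+4)

    Neighbor distances to the adjacent motif site on each side are recorded
    for the short-fragment filter; chromosomes in ``circular`` wrap.
    """
    if motif != "GATC":
        raise ValueError("half-site counting is defined for the GATC motif")
    frag = fragments
    if {"chrom", "start", "end"} - set(frag.columns):
        raise ValueError("fragments need columns chrom, start, end")
    if (frag["start"] >= frag["end"]).any():
        raise ValueError("fragments must satisfy start < end")

    out_frames = []
    frag_by_chrom = dict(tuple(frag.groupby("chrom", sort=False)))
    for chrom, sgrp in sites.groupby("chrom", sort=False):
        pos = sgrp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"{chrom}: site positions must be sorted ascending")
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"{chrom}: duplicate site positions")
        f = frag_by_chrom.get(chrom)
        if f is None:
            s = np.empty(0, dtype=np.int64)
            e = np.empty(0, dtype=np.int64)
        else:
            s = f["start"].to_numpy(np.int64)
            e = f["end"].to_numpy(np.int64)

        def exact(coords: np.ndarray, targets: np.ndarray) -> np.ndarray:
            if coords.size == 0:
                return np.zeros(targets.size, dtype=np.int64)
            u, c = np.unique(coords, return_counts=True)
            idx = np.searchsorted(u, targets)
            idx = np.clip(idx, 0, u.size - 1)
            hit = u[idx] == targets
            return np.where(hit, c[idx], 0)

        ends_at_G = exact(e, pos + 1)
        ends_at_A = exact(e, pos + 2)
        starts_at_T = exact(s, pos + 2)
        starts_at_C = exact(s, pos + 3)

        # cov: start <= a and end >= b, counted per site.  Sites are few
        # relative to fragments, so a chunked boolean reduction is fine.
        def cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            out = np.zeros(a.size, dtype=np.int64)
            if s.size == 0:
                return out
            for i in range(a.size):
                out[i] = int(np.count_nonzero((s <= a[i]) & (e >= b[i])))
            return out

        cov_G = cov(pos, pos + 2)
        cov_C = cov(pos + 2, pos + 4)

        clen = None if chrom_lengths is None else chrom_lengths.get(chrom)
        left, right = _neighbor_distances(pos, clen, chrom in circular)

        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ends_at_G": ends_at_G,
                    "ends_at_A": ends_at_A,
                    "starts_at_T": starts_at_T,
                    "starts_at_C": starts_at_C,
                    "cov_G": cov_G,
                    "cov_C": cov_C,
                    "neighbor_dist_left": left,
                    "neighbor_dist_right": right,
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "ends_at_G", "ends_at_A", "starts_at_T",
                     "starts_at_C", "cov_G", "cov_C",
                     "neighbor_dist_left", "neighbor_dist_right"]
        )
    return pd.concat(out_frames, ignore_index=True)


def quantify_fractions(
    counts: pd.DataFrame, min_neighbor_bp: int = MIN_NEIGHBOR_BP
) -> pd.DataFrame:
    """Pool valid half-site counts into per-site methylated fractions.

    A half-site is valid when its neighboring site on the fragment side is
    at least ``min_neighbor_bp`` away.  The site fraction pools counts over
    valid half-sites (sum of numerators / sum of denominators), weighting
    each strand's evidence by its coverage.  Sites with no valid half-site
    or zero pooled coverage are dropped.  Ratios above 1 (possible when
    trimmed ends deflate the protection denominator) are clipped with a
    warning.
    """
    left_valid = counts["neighbor_dist_left"].to_numpy() >= min_neighbor_bp
    right_valid = counts["neighbor_dist_right"].to_numpy() >= min_neighbor_bp
    num_l = (counts["ends_at_G"] + counts["ends_at_A"]).to_numpy(float)
    num_r = (counts["starts_at_T"] + counts["starts_at_C"]).to_numpy(float)
    den_l = counts["cov_G"].to_numpy(float)
    den_r = counts["cov_C"].to_numpy(float)

    num = np.where(left_valid, num_l, 0.0) + np.where(right_valid, num_r, 0.0)
    den = np.where(left_valid, den_l, 0.0) + np.where(right_valid, den_r, 0.0)
    keep = (left_valid | right_valid) & (den > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(keep, num / np.where(den > 0, den, 1.0), np.nan)
    over = keep & (frac > 1.0)
    if over.any():
        warnings.warn(f"{int(over.sum())} site fraction(s) > 1 clipped to 1",
                      RuntimeWarning, stacklevel=2)
        frac = np.minimum(frac, 1.0)

    out = counts[["chrom", "pos"]].copy()
    out["left_valid"] = left_valid
    out["right_valid"] = right_valid
    out["fraction"] = frac
    out["retained"] = keep
    return out
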