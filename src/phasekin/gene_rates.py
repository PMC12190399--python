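"""Per-gene bias-corrected methylation rates and rate quintiles.

The plain mean of a gene's site rates is biased because sites sample the
oscillating population-average landscape unevenly: a gene whose sites
happen to sit in linkers looks fast regardless of its chromatin.  The
correction subtracts, per gene, the mean of the population fitted curve
at the gene's own site offsets (relative to the population mean), leaving
the gene's mean deviation from the curve anchored at the population
adjusted mean rate.  Genes are then ranked and split into quintiles
(Q1 = slowest), and the phasing model is refit per quintile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sinefit import DEFAULT_FIT_RANGE, FitReport, SinePhaseParams, sine_eval
from .phasing import phase_fit, site_offsets

__all__ = ["gene_unbiased_rates", "assign_quintiles", "quintile_phase_fits",
           "N_MIN_SITES"]

#: Minimum sites inside the fit window for a gene to be ranked.
N_MIN_SITES = 5


def gene_unbiased_rates(
    norm_rates,
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    pop_params: SinePhaseParams,
    pop_adj_mean: float,
    fit_range=DEFAULT_FIT_RANGE,
    n_min: int = N_MIN_SITES,
) -> pd.DataFrame:
    """Bias-corrected mean rate per gene.

    For each gene: ``raw_mean`` is the mean normalized rate of its sites
    with offsets inside the fit window; ``bias`` is the mean fitted-curve
    value at those offsets minus the population adjusted mean; and
    ``unbiased_rate = raw_mean − bias`` (equivalently, the gene's mean
    deviation from the curve plus the population mean).  Genes with fewer
    than ``n_min`` sites are emitted but flagged unrankable.
    """
    lo, hi = fit_range
    assignments = site_offsets(sites, genes, window=(lo, hi))
    v = np.asarray(norm_rates, dtype=float)[assignments["site_idx"].to_numpy()]
    off = assignments["offset"].to_numpy()
    curve = sine_eval(pop_params, off)
    df = pd.DataFrame({"gene_id": assignments["gene_id"], "value": v, "curve": curve})
    df = df[np.isfinite(df["value"])]
    agg = df.groupby("gene_id").agg(
        n_sites=("value", "size"), raw_mean=("value", "mean"), curve_mean=("curve", "mean")
    )
    agg["bias"] = agg["curve_mean"] - pop_adj_mean
    agg["unbiased_rate"] = agg["raw_mean"] - agg["bias"]
    agg["rankable"] = agg["n_sites"] >= n_min
    out = agg.reset_index()[["gene_id", "n_sites", "raw_mean", "bias",
                             "unbiased_rate", "rankable"]]
    return out.sort_values("gene_id", ignore_index=True)


def assign_quintiles(records: pd.DataFrame) -> pd.DataFrame:
    """Label rankable genes Q1..Q5 by ascending unbiased rate.

    Group sizes differ by at most one (the first groups take the extra
    gene when the count is not divisible by five); ties are broken by
    gene_id so the split is deterministic.  Q1 = slowest.  Unrankable
    genes get quintile 0.
    """
    out = records.copy()
    out["quintile"] = 0
    ranked = out[out["rankable"]].sort_values(
        ["unbiased_rate", "gene_id"], kind="stable"
    )
    n = len(ranked)
    if n < 5:
        raise ValueError(f"need at least 5 rankable genes, got {n}")
    q, r = divmod(n, 5)
    sizes = [q + 1] * r + [q] * (5 - r)
    labels = np.repeat(np.arange(1, 6), sizes)
    out.loc[ranked.index, "quintile"] = labels
    return out


def quintile_phase_fits(
    records: pd.DataFrame,
    norm_rates,
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    fit_range=DEFAULT_FIT_RANGE,
    min_points: int = 50,
) -> list[FitReport]:
    """Refit the phasing model on the combined data of each quintile.

    Returns five fit reports ordered Q1 (slowest) to Q5 (fastest).
    """
    reports = []
    for qi in range(1, 6):
        subset = records.loc[records["quintile"] == qi, "gene_id"].tolist()
        report, _ = phase_fit(
            norm_rates, sites, genes, gene_subset=subset,
            fit_range=fit_range, min_points=min_points,
        )
        reports.append(report)
    return reports
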