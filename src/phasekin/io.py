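"""File formats: gene tables, site catalogs, fragments, fractions, rates.

All interval I/O is 0-based half-open (BED / bedGraph dialect).  TSV
outputs carry a header and a tool-version comment line.  The gene table
convention: ``tss`` is the genomic position of the first transcribed
base; ``end`` is the gene-oriented exclusive end (``tss + length`` on the
plus strand, ``tss − length`` on the minus strand); ``introns`` is a
semicolon-separated list of genomic ``start-end`` pairs (half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_genes", "write_genes", "read_bed", "write_bed",
    "read_bedgraph", "write_bedgraph", "read_fractions", "write_tsv",
    "read_config", "GENE_COLUMNS",
]

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "plus1_dyad", "end",
                "klass", "introns"]

_VERSION_COMMENT = f"# phasekin v{__version__}"


def write_tsv(df: pd.DataFrame, path) -> None:
    """TSV with header and a tool-version comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VERSION_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_genes(genes: pd.DataFrame, path) -> None:
    write_tsv(genes[GENE_COLUMNS].fillna({"introns": ""}), path)


def read_genes(path) -> pd.DataFrame:
    """Validated gene annotation table.

    Raises on a malformed or duplicated record, naming the offending line.
    """
    df = _read_tsv(path)
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene columns {sorted(missing)}")
    df = df[GENE_COLUMNS].copy()
    df["introns"] = df["introns"].fillna("").astype(str)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene_id {df.loc[dup, 'gene_id'].iloc[0]!r}")
    for i, row in enumerate(df.itertuples(index=False), start=3):  # 1 comment + 1 header
        if row.strand not in ("+", "-"):
            raise ValueError(f"{path}:{i}: invalid strand {row.strand!r}")
        for field in ("tss", "plus1_dyad", "end"):
            v = getattr(row, field)
            if not np.isfinite(v) or int(v) != v or v < 0:
                raise ValueError(f"{path}:{i}: invalid {field} {v!r}")
        if row.introns:
            for iv in row.introns.split(";"):
                parts = iv.split("-")
                if len(parts) != 2 or not all(p.isdigit() for p in parts) \
                        or int(parts[0]) >= int(parts[1]):
                    raise ValueError(f"{path}:{i}: malformed intron interval {iv!r}")
    for c in ("tss", "plus1_dyad", "end"):
        df[c] = df[c].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    """3-column BED (plus optional name column), 0-based half-open."""
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df


def write_sites_bed(sites: pd.DataFrame, path, motif_len: int = 4) -> None:
    out = sites[["chrom", "pos"]].copy()
    out["start"] = out["pos"]
    out["end"] = out["pos"] + motif_len
    write_bed(out, path)


def read_sites_bed(path) -> pd.DataFrame:
    bed = read_bed(path)
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"].astype(np.int64)}) \
        .sort_values(["chrom", "pos"], ignore_index=True)


def write_bedgraph(sites: pd.DataFrame, values, path, span: int = 1) -> None:
    """Per-site values as bedGraph intervals of ``span`` bp at each site."""
    v = np.asarray(values, dtype=float)
    out = pd.DataFrame(
        {"chrom": sites["chrom"], "start": sites["pos"],
         "end": sites["pos"] + span, "value": v}
    )
    out = out[np.isfinite(out["value"])]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


def read_fractions(paths, sites: pd.DataFrame, times) -> np.ndarray:
    """Assemble a (site × time) fraction matrix from per-timepoint bedGraphs.

    Sites absent from a track get NaN at that timepoint.  Fractions
    outside [0, 1] are rejected, naming the site.
    """
    paths = list(paths)
    times = list(times)
    if len(paths) != len(times):
        raise ValueError(f"{len(paths)} tracks but {len(times)} timepoints")
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    mat = np.full((len(sites), len(times)), np.nan)
    for j, p in enumerate(paths):
        bg = read_bedgraph(p)
        bad = bg[(bg["value"] < 0) | (bg["value"] > 1)]
        if not bad.empty:
            r = bad.iloc[0]
            raise ValueError(
                f"{p}: fraction {r['value']} outside [0,1] at {r['chrom']}:{int(r['start'])}")
        s = pd.Series(bg["value"].to_numpy(),
                      index=pd.MultiIndex.from_frame(bg[["chrom", "start"]]))
        s = s[~s.index.duplicated(keep="first")]
        mat[:, j] = s.reindex(key).to_numpy()
    return mat


def read_config(path) -> dict:
    """Flat key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg
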