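"""Nearest-gene annotation and coordinate conventions.

Probe positions are 1-based points; gene bodies are 0-based half-open
intervals (BED convention).  Distance is 0 when the probe lies inside a
gene body, otherwise the gap to the nearest interval edge on the same
chromosome; ties go to the alphabetically first symbol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENE_COLUMNS = ["symbol", "chrom", "start", "end"]


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if not set(GENE_COLUMNS).issubset(genes.columns):
        raise ValueError(f"gene table needs columns {GENE_COLUMNS}")
    if (genes["end"] <= genes["start"]).any():
        bad = genes[genes["end"] <= genes["start"]]
        raise ValueError(f"gene interval end <= start: {bad['symbol'].tolist()[:5]}")
    return genes.drop_duplicates(subset=GENE_COLUMNS)


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame):
    """Nearest gene symbol and distance in bp for a 1-based probe position.

    Returns ``(None, nan)`` when the chromosome carries no genes.
    """
    genes = validate_genes(genes)
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None, float("nan")
    # probe base at 1-based pos occupies [pos-1, pos) in 0-based half-open
    start = sub["start"].to_numpy(np.int64)
    end = sub["end"].to_numpy(np.int64)
    p0 = pos - 1
    inside = (start <= p0) & (p0 < end)
    dist = np.where(inside, 0, np.maximum(start - p0, p0 - (end - 1)))
    dist = np.maximum(dist, 0)
    best = dist.min()
    symbols = sorted(sub["symbol"].to_numpy()[dist == best])
    return symbols[0], int(best)


def annotate_probes(annotation: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Add nearest_gene / dist_bp / dist_kb columns to a probe annotation
    table (columns chrom, pos)."""
    genes = validate_genes(genes)
    out = annotation.copy()
    syms, dists = [], []
    by_chrom = {c: sub for c, sub in genes.groupby("chrom", sort=False)}
    for chrom, pos in zip(out["chrom"], out["pos"]):
        sub = by_chrom.get(chrom)
        if sub is None:
            syms.append(None)
            dists.append(np.nan)
        else:
            s, d = nearest_gene(chrom, int(pos), sub)
            syms.append(s)
            dists.append(d)
    out["nearest_gene"] = syms
    out["dist_bp"] = dists
    out["dist_kb"] = np.round(np.asarray(dists, float) / 1000.0, 1)
    return out
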