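"""Spatial combination of EWAS p-values into differentially methylated
regions (DMRs), comb-p style.

Stages:

1. :func:`estimate_acf` — correlation of probit-transformed p-values as a
   function of genomic distance, in contiguous distance bins.
2. :func:`slk_smooth` — Stouffer–Liptak–Kechris smoothing: each probe's p is
   combined with its neighbours within a window, using the binned
   autocorrelation to build the correlation matrix.
3. :func:`find_regions` — seed a region at a smoothed p below the seed
   threshold and extend while further seeding probes lie within ``dist`` bp.
4. :func:`score_region` — Stouffer–Liptak combination of the member probes'
   raw p-values.
5. :func:`sidak_correct` — multiple-region correction
   1 - (1 - p)^(total_covered / region_length).

Probe positions are 1-based points internally; emitted regions use BED
0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def make_track(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a per-probe p-value track.

    ``df`` needs columns chrom, pos (1-based point), p_raw; index = probe id.
    Positions must be unique within a chromosome.
    """
    need = {"chrom", "pos", "p_raw"}
    if not need.issubset(df.columns):
        raise ValueError(f"track needs columns {sorted(need)}")
    track = df.dropna(subset=["p_raw"]).sort_values(
        ["chrom", "pos"], kind="stable"
    )
    dup = track.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError(
            f"duplicate positions within a chromosome: "
            f"{track.index[dup][:5].tolist()}"
        )
    return track


@dataclass
class AcfEstimate:
    """Binned distance autocorrelation of probit(p)."""

    bins: list          # (lo, hi) inclusive distance windows in bp
    rho: np.ndarray     # correlation per bin, clipped to [0, 1)
    n_pairs: np.ndarray

    def rho_at(self, dist: np.ndarray) -> np.ndarray:
        """Correlation for arbitrary distances (>= 1); distances beyond the
        last bin use the last bin's value."""
        dist = np.asarray(dist)
        lo0 = self.bins[0][0]
        width = self.bins[0][1] - self.bins[0][0] + 1
        idx = np.clip((dist - lo0) // width, 0, len(self.bins) - 1).astype(int)
        return self.rho[idx]


def _z_from_p(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, P_FLOOR, P_CEIL))


def estimate_acf(track: pd.DataFrame, max_dist: int = 500,
                 bin_size: int = 50) -> AcfEstimate:
    """Distance-binned Pearson correlation of z = probit(1 - p) over all
    same-chromosome probe pairs separated by <= ``max_dist`` bp.

    Negative estimates are clipped to 0; empty bins inherit the previous
    bin's value (the first defaults to 0).
    """
    track = make_track(track)
    if len(track) < 2:
        raise ValueError("need >= 2 probes to estimate the ACF")
    bins = []
    lo = 1
    while lo <= max_dist:
        bins.append((lo, min(lo + bin_size - 1, max_dist)))
        lo += bin_size
    pair_z1 = [[] for _ in bins]
    pair_z2 = [[] for _ in bins]
    width = bin_size
    for _, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        z = _z_from_p(sub["p_raw"].to_numpy(float))
        n = len(pos)
        j = 0
        for i in range(n):
            if j <= i:
                j = i + 1
            while j < n and pos[j] - pos[i] <= max_dist:
                j += 1
            for jj in range(i + 1, j):
                d = pos[jj] - pos[i]
                b = min((d - 1) // width, len(bins) - 1)
                pair_z1[b].append(z[i])
                pair_z2[b].append(z[jj])
    rho = np.zeros(len(bins))
    n_pairs = np.zeros(len(bins), dtype=int)
    prev = 0.0
    for b in range(len(bins)):
        n_pairs[b] = len(pair_z1[b])
        if n_pairs[b] >= 2:
            a1 = np.asarray(pair_z1[b])
            a2 = np.asarray(pair_z2[b])
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(a1, a2)[0, 1]
            if not np.isfinite(r):
                r = prev
        else:
            r = prev
        rho[b] = min(max(r, 0.0), 1.0 - 1e-9)
        prev = rho[b]
    return AcfEstimate(bins=bins, rho=rho, n_pairs=n_pairs)


def _repair_sigma(sigma: np.ndarray) -> np.ndarray:
    """Eigenvalue-floor repair of a non-PSD correlation matrix, rescaled
    back to unit diagonal."""
    w, V = np.linalg.eigh(sigma)
    w = np.maximum(w, 1e-10)
    S = (V * w) @ V.T
    dinv = 1.0 / np.sqrt(np.diag(S))
    return S * np.outer(dinv, dinv)


def stouffer_liptak(pvals, sigma=None) -> float:
    """Correlation-adjusted Stouffer combination of p-values.

    z_i = probit(1 - p_i); combined z = sum(z) / sqrt(1' sigma 1);
    returns the upper tail 1 - Phi(z_comb).  ``sigma=None`` means
    independence.  A single p-value is returned unchanged.
    """
    p = np.clip(np.asarray(pvals, float), P_FLOOR, P_CEIL)
    k = len(p)
    if k == 0:
        raise ValueError("need at least one p-value")
    if k == 1:
        return float(p[0])
    if sigma is None:
        sigma = np.eye(k)
    sigma = np.asarray(sigma, float)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = _repair_sigma(sigma)
    denom = np.sqrt(np.sum(sigma))
    z = _z_from_p(p)
    z_comb = z.sum() / denom
    return float(np.clip(stats.norm.sf(z_comb), P_FLOOR, 1.0))


def _sigma_from_positions(pos: np.ndarray, acf: AcfEstimate) -> np.ndarray:
    d = np.abs(pos[:, None] - pos[None, :])
    sigma = np.where(d == 0, 1.0, acf.rho_at(np.maximum(d, 1)))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def slk_smooth(track: pd.DataFrame, acf: AcfEstimate, dist: int = 500) -> pd.Series:
    """Per-probe smoothed p: combine each probe's raw p with all
    same-chromosome neighbours within ±``dist`` bp (Stouffer–Liptak with the
    ACF-derived correlation matrix).  Isolated probes keep their raw p.
    """
    track = make_track(track)
    out = pd.Series(np.nan, index=track.index, dtype=float)
    for _, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        p = sub["p_raw"].to_numpy(float)
        ids = sub.index
        lo = np.searchsorted(pos, pos - dist, side="left")
        hi = np.searchsorted(pos, pos + dist, side="right")
        for i in range(len(pos)):
            a, b = lo[i], hi[i]
            if b - a == 1:
                out[ids[i]] = p[i]
            else:
                sigma = _sigma_from_positions(pos[a:b], acf)
                out[ids[i]] = stouffer_liptak(p[a:b], sigma)
    return out


def find_regions(track: pd.DataFrame, adjusted_p: pd.Series,
                 seed: float = 0.05, dist: int = 500) -> list[dict]:
    """Seed-and-extend region finding on the smoothed p track.

    A region opens at a probe with adjusted p < ``seed`` and extends while
    the next seeding probe lies within ``dist`` bp of the region's last
    seeding member.  Interior non-seeding probes are skipped for extension
    but included as members when inside the final span.  Regions need >= 2
    seeding probes.
    """
    track = make_track(track)
    regions = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        padj = adjusted_p.loc[sub.index].to_numpy(float)
        ids = sub.index.to_numpy()
        seed_idx = np.flatnonzero(padj < seed)
        if len(seed_idx) == 0:
            continue
        group = [seed_idx[0]]
        groups = []
        for i in seed_idx[1:]:
            if pos[i] - pos[group[-1]] <= dist:
                group.append(i)
            else:
                groups.append(group)
                group = [i]
        groups.append(group)
        for g in groups:
            if len(g) < 2:
                continue
            lo_pos, hi_pos = pos[g[0]], pos[g[-1]]
            member_mask = (pos >= lo_pos) & (pos <= hi_pos)
            regions.append(
                {
                    "chrom": chrom,
                    "start_pos": int(lo_pos),   # 1-based first member
                    "end_pos": int(hi_pos),     # 1-based last member
                    "probe_ids": ids[member_mask].tolist(),
                    "seed_probe_ids": ids[g].tolist(),
                }
            )
    return regions


def score_region(region: dict, track: pd.DataFrame, acf: AcfEstimate) -> float:
    """Stouffer–Liptak combination of the member probes' raw p-values with
    the ACF-derived correlation matrix."""
    sub = track.loc[region["probe_ids"]]
    if len(sub) < 2:
        raise ValueError("region needs >= 2 member probes")
    sigma = _sigma_from_positions(sub["pos"].to_numpy(np.int64), acf)
    return stouffer_liptak(sub["p_raw"].to_numpy(float), sigma)


def sidak_correct(p_region: float, region_len_bp: int,
                  total_covered_bp: int) -> float:
    """Šidák-style correction 1 - (1 - p)^(total_covered / region_len),
    computed through log1p/expm1 so tiny p-values do not underflow."""
    if region_len_bp < 1:
        raise ValueError("region length must be >= 1 bp")
    if total_covered_bp < region_len_bp:
        raise ValueError("total covered bases must be >= region length")
    ratio = total_covered_bp / region_len_bp
    p = min(max(p_region, 0.0), P_CEIL)
    return float(-np.expm1(ratio * np.log1p(-p)))


def total_covered_bases(track: pd.DataFrame, dist: int = 500) -> int:
    """Total bases 'covered' by the tested probes: per probe, the smaller of
    the gap to the next same-chromosome probe and ``dist``; the final probe
    on each chromosome contributes ``dist``."""
    track = make_track(track)
    total = 0
    for _, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        if len(pos) == 1:
            total += dist
            continue
        gaps = np.minimum(np.diff(pos), dist)
        total += int(gaps.sum()) + dist
    return total


@dataclass
class DmrRecord:
    """A called region in BED 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    n_probes: int
    n_seeds: int
    probe_ids: list
    p_region: float
    p_sidak: float
    mean_delta_beta: dict = field(default_factory=dict)  # contrast -> mean Δβ

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.n_probes < 2:
            raise ValueError("a region needs >= 2 probes")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def call_dmrs(ewas_result, contrast: str, seed: float = 0.05, dist: int = 500,
              max_dist: int = 500, bin_size: int = 50,
              sidak_alpha: float = 0.05,
              delta_beta_tables: dict | None = None):
    """Full DMR pipeline for one contrast of an EWAS result.

    Runs ACF estimation, Stouffer–Liptak–Kechris smoothing, seed-and-extend
    region finding, region scoring and Šidák correction, then attaches the
    mean Δβ across member probes for every contrast available.

    Returns
    -------
    (significant, all_records) — lists of :class:`DmrRecord`; ``significant``
    keeps p_sidak < ``sidak_alpha``.
    """
    track = make_track(ewas_result.pval_track(contrast))
    if delta_beta_tables is None:
        delta_beta_tables = {
            name: t["coef_beta"]
            for name, t in ewas_result.tables.items()
            if "coef_beta" in t.columns
        }
    acf = estimate_acf(track, max_dist=max_dist, bin_size=bin_size)
    adjusted = slk_smooth(track, acf, dist=dist)
    candidates = find_regions(track, adjusted, seed=seed, dist=dist)
    covered = total_covered_bases(track, dist=dist)
    records = []
    for region in candidates:
        p_reg = score_region(region, track, acf)
        start = region["start_pos"] - 1          # BED half-open
        end = region["end_pos"]
        p_sid = sidak_correct(p_reg, end - start, max(covered, end - start))
        mean_db = {
            name: float(vals.reindex(region["probe_ids"]).mean())
            for name, vals in delta_beta_tables.items()
        }
        records.append(
            DmrRecord(
                chrom=region["chrom"],
                start=start,
                end=end,
                n_probes=len(region["probe_ids"]),
                n_seeds=len(region["seed_probe_ids"]),
                probe_ids=region["probe_ids"],
                p_region=p_reg,
                p_sidak=p_sid,
                mean_delta_beta=mean_db,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start))
    significant = [r for r in records if r.p_sidak < sidak_alpha]
    return significant, records


def dmr_table(records: list[DmrRecord]) -> pd.DataFrame:
    """Tabular mirror of the record list (one row per region)."""
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_probes": r.n_probes, "n_seeds": r.n_seeds,
            "p_region": r.p_region, "p_sidak": r.p_sidak,
        }
        for name, v in r.mean_delta_beta.items():
            row[f"mean_delta_beta_{name}"] = v
        rows.append(row)
    cols = ["chrom", "start", "end", "n_probes", "n_seeds", "p_region", "p_sidak"]
    if rows:
        extra = [c for c in rows[0] if c not in cols]
        cols = cols + extra
    return pd.DataFrame(rows, columns=cols)
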