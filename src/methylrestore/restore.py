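"""Selection of "restored" CpGs and DMRs: loci shifted by maternal smoking
(placebo vs never-smoker contrast, Δβ_PN) whose treatment effect (vitamin C
vs placebo, Δβ_VP) points in the opposite direction.

Percent restored = (-Δβ_VP / Δβ_PN) × 100: 100% means the treatment exactly
cancels the smoking shift, values above 100% indicate overshoot.  Values are
reported unclamped; a flag caps them to [0, 100] for summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combp import DmrRecord


def overlap_nominal(res_pn, res_vp, alpha: float = 0.05) -> list:
    """Probes nominally significant (raw p strictly below ``alpha``) in BOTH
    contrasts.  ``res_pn``/``res_vp`` are per-probe tables (or an
    EwasResults' ``table()`` output) carrying ``p_raw``."""
    t_pn = res_pn if isinstance(res_pn, pd.DataFrame) else res_pn.table("PN")
    t_vp = res_vp if isinstance(res_vp, pd.DataFrame) else res_vp.table("VP")
    if not t_pn.index.sort_values().equals(t_vp.index.sort_values()):
        only_pn = t_pn.index.difference(t_vp.index)
        only_vp = t_vp.index.difference(t_pn.index)
        raise ValueError(
            f"probe universes differ: {len(only_pn)} only in PN "
            f"(e.g. {only_pn[:3].tolist()}), {len(only_vp)} only in VP "
            f"(e.g. {only_vp[:3].tolist()})"
        )
    sig_pn = t_pn.index[t_pn["p_raw"] < alpha]
    sig_vp = t_vp.index[t_vp["p_raw"] < alpha]
    return sig_pn.intersection(sig_vp).tolist()


def classify_restoration(delta_beta_pn, delta_beta_vp):
    """Direction-reversal classification and percent restored.

    restored is true iff the two deltas are nonzero with opposite signs;
    percent restored = (-Δβ_VP / Δβ_PN) × 100 (NaN when Δβ_PN = 0).
    Accepts scalars or arrays.
    """
    d_pn = np.asarray(delta_beta_pn, float)
    d_vp = np.asarray(delta_beta_vp, float)
    restored = (np.sign(d_vp) == -np.sign(d_pn)) & (d_pn != 0) & (d_vp != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(d_pn != 0, -d_vp / d_pn * 100.0, np.nan)
    if np.ndim(delta_beta_pn) == 0:
        return bool(restored), float(percent)
    return restored, percent


def select_candidates(res_pn, res_vp, alpha: float = 0.05,
                      cap_percent: bool = False):
    """Candidate restored CpGs: the nominal-overlap set, kept only where the
    beta-scale deltas reverse direction.

    Returns
    -------
    (candidates, audit) — DataFrames with columns delta_beta_PN,
    delta_beta_VP, p_PN, p_VP, restored, percent_restored; ``audit`` holds
    the full overlap set including the non-restored remainder.
    """
    t_pn = res_pn if isinstance(res_pn, pd.DataFrame) else res_pn.table("PN")
    t_vp = res_vp if isinstance(res_vp, pd.DataFrame) else res_vp.table("VP")
    overlap = overlap_nominal(t_pn, t_vp, alpha)
    d_pn = t_pn.loc[overlap, "coef_beta"]
    d_vp = t_vp.loc[overlap, "coef_beta"]
    restored, percent = classify_restoration(d_pn.to_numpy(), d_vp.to_numpy())
    if cap_percent:
        percent = np.clip(percent, 0.0, 100.0)
    audit = pd.DataFrame(
        {
            "delta_beta_PN": d_pn,
            "delta_beta_VP": d_vp,
            "p_PN": t_pn.loc[overlap, "p_raw"],
            "p_VP": t_vp.loc[overlap, "p_raw"],
            "restored": restored,
            "percent_restored": percent,
        },
        index=pd.Index(overlap, name="probe_id"),
    )
    return audit[audit["restored"]].copy(), audit


@dataclass
class RestoredDmr:
    """A treatment-contrast DMR overlapping a smoking-contrast DMR."""

    vp_dmr: DmrRecord
    np_dmr: DmrRecord
    overlap_bp: int
    shared_probes: list
    mean_delta_beta_vp: float
    mean_delta_beta_pn: float
    mean_percent_restored: float

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap must be >= 1 bp")


def restored_dmrs(dmrs_vp: list[DmrRecord], dmrs_np: list[DmrRecord],
                  delta_beta_vp: pd.Series | None = None,
                  delta_beta_pn: pd.Series | None = None) -> list[RestoredDmr]:
    """Interval intersection (half-open, >= 1 bp overlap) of treatment DMRs
    with smoking DMRs; Δβ and percent restored are averaged over the probes
    the two regions share (falling back to the VP region's stored means when
    per-probe deltas are not supplied)."""
    out = []
    for v in dmrs_vp:
        for n in dmrs_np:
            if v.chrom != n.chrom:
                continue
            ov = min(v.end, n.end) - max(v.start, n.start)
            if ov < 1:
                continue
            shared = sorted(set(v.probe_ids) & set(n.probe_ids))
            if delta_beta_vp is not None and shared:
                d_vp = float(delta_beta_vp.reindex(shared).mean())
                d_pn = float(delta_beta_pn.reindex(shared).mean())
            else:
                d_vp = v.mean_delta_beta.get("VP", np.nan)
                d_pn = v.mean_delta_beta.get("PN", np.nan)
            pct = -d_vp / d_pn * 100.0 if d_pn else np.nan
            out.append(
                RestoredDmr(
                    vp_dmr=v, np_dmr=n, overlap_bp=int(ov),
                    shared_probes=shared,
                    mean_delta_beta_vp=d_vp, mean_delta_beta_pn=d_pn,
                    mean_percent_restored=pct,
                )
            )
    return out


def restored_dmr_table(pairs: list[RestoredDmr]) -> pd.DataFrame:
    """Tabular mirror: chrom, start, end, n CpGs, Šidák p, mean Δβ per
    contrast and % restored for each overlapping region pair."""
    rows = [
        {
            "chrom": p.vp_dmr.chrom,
            "start": p.vp_dmr.start,
            "end": p.vp_dmr.end,
            "n_cpgs": p.vp_dmr.n_probes,
            "p_sidak": p.vp_dmr.p_sidak,
            "overlap_bp": p.overlap_bp,
            "mean_delta_beta_VP": p.mean_delta_beta_vp,
            "mean_delta_beta_PN": p.mean_delta_beta_pn,
            "percent_restored": p.mean_percent_restored,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_cpgs", "p_sidak", "overlap_bp",
            "mean_delta_beta_VP", "mean_delta_beta_PN", "percent_restored",
        ],
    )


def replication_lookup(internal: pd.DataFrame, external: pd.DataFrame,
                       alpha: float = 0.05, fdr_col: str = "p_bh") -> dict:
    """Concordance of beta-scale coefficients with an external EWAS.

    ``internal`` is a per-probe table with ``coef_beta``, ``p_raw`` (and
    optionally ``p_bh``); ``external`` has ``coef_beta`` and optionally
    ``p_raw``/``p_bh``, indexed by probe id.

    Returns a report dict: shared probe count, nominal-in-both count,
    direction concordance among nominal-in-both, Pearson and Spearman
    correlations of the coefficients over shared nominal probes, and the
    same restricted to FDR-significant probes where available.
    """
    shared = internal.index.intersection(external.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared probes; need >= 10")
    a = internal.loc[shared]
    b = external.loc[shared]
    report: dict = {"n_shared": int(len(shared))}

    def _concordance(mask) -> dict:
        ids = shared[np.asarray(mask, bool)]
        out = {"n": int(len(ids))}
        if len(ids) >= 2:
            ca = a.loc[ids, "coef_beta"].to_numpy(float)
            cb = b.loc[ids, "coef_beta"].to_numpy(float)
            out["direction_concordance"] = float(
                np.mean(np.sign(ca) == np.sign(cb))
            )
            out["pearson_r"] = float(np.corrcoef(ca, cb)[0, 1])
            out["spearman_r"] = float(
                pd.Series(ca).corr(pd.Series(cb), method="spearman")
            )
        return out

    nominal = (a["p_raw"] < alpha).to_numpy()
    if "p_raw" in b.columns:
        nominal &= (b["p_raw"] < alpha).to_numpy()
    report["nominal_in_both"] = _concordance(nominal)
    if fdr_col in a.columns and fdr_col in b.columns:
        fdr = (a[fdr_col] < alpha).to_numpy() & (b[fdr_col] < alpha).to_numpy()
        report["fdr_in_both"] = _concordance(fdr)
    return report
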