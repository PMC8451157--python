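"""Cis-window expression quantitative trait methylation (eQTM).

Candidate CpGs are paired with every transcript whose TSS lies within a
window (default ±250 kb, boundary inclusive) on the same chromosome.  Both
the CpG beta values and the log-CPM expression are residualized against the
shared covariates (infant sex, cell-type proportions, gestational age;
RNA batch on the expression side by default), then each pair is tested by
simple linear regression of the expression residual on the methylation
residual, with BH-FDR across all tested pairs jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import adjust_pvalues


def build_covariate_design(samples: pd.DataFrame,
                           cell_props: pd.DataFrame | None = None,
                           include_batch: bool = False) -> pd.DataFrame:
    """Intercept + infant sex + gestational age (+ leading k-1 cell
    proportions, + RNA batch when requested), indexed like ``samples``."""
    cols = {"intercept": np.ones(len(samples))}
    if "infant_sex" in samples.columns:
        cols["sex_M"] = (samples["infant_sex"] == "M").astype(float).to_numpy()
    if "ga_weeks" in samples.columns:
        ga = samples["ga_weeks"].astype(float)
        cols["ga_weeks"] = (ga - ga.mean()).to_numpy()
    X = pd.DataFrame(cols, index=samples.index)
    if cell_props is not None:
        cp = cell_props.loc[samples.index]
        for c in cp.columns[:-1]:
            X[f"prop_{c}"] = cp[c].astype(float).to_numpy()
    if include_batch and "rna_batch" in samples.columns:
        batches = sorted(samples["rna_batch"].unique())
        for b in batches[1:]:
            X[f"batch_{b}"] = (samples["rna_batch"] == b).astype(float).to_numpy()
    return X


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Row-wise OLS residuals of ``matrix`` (features x samples) against the
    covariate design (samples x p, intercept included by the caller)."""
    X = covariates.loc[matrix.columns].to_numpy(float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via QR pivot magnitudes
        _, R = np.linalg.qr(X)
        bad = [covariates.columns[j] for j in range(p) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    Y = matrix.to_numpy(float)
    coef = np.linalg.solve(X.T @ X, X.T @ Y.T)
    resid = Y - (X @ coef).T
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def pair_cis(probe_annotation: pd.DataFrame, transcript_annotation: pd.DataFrame,
             window: int = 250_000) -> pd.DataFrame:
    """All same-chromosome (probe, transcript) pairs with
    |tss_pos - probe pos| <= ``window`` (inclusive); strand is ignored.

    Returns a DataFrame with probe_id, transcript_id, distance_bp.
    """
    rows = []
    tx_by_chrom = {
        c: sub.sort_values("tss_pos")
        for c, sub in transcript_annotation.groupby("chrom", sort=False)
    }
    for chrom, probes in probe_annotation.groupby("chrom", sort=False):
        tx = tx_by_chrom.get(chrom)
        if tx is None:
            continue
        tss = tx["tss_pos"].to_numpy(np.int64)
        tx_ids = tx.index.to_numpy()
        for pid, pos in probes["pos"].items():
            lo = np.searchsorted(tss, pos - window, side="left")
            hi = np.searchsorted(tss, pos + window, side="right")
            for j in range(lo, hi):
                rows.append((pid, tx_ids[j], int(abs(tss[j] - pos))))
    return pd.DataFrame(rows, columns=["probe_id", "transcript_id", "distance_bp"])


def associate_eqtm(pairs: pd.DataFrame, meth_resid: pd.DataFrame,
                   expr_resid: pd.DataFrame) -> pd.DataFrame:
    """Simple linear regression of expression residual on methylation
    residual (beta scale) for every pair; two-sided p, BH-FDR jointly
    across all tested pairs.  Pairs whose methylation residual has zero
    variance are skipped (flagged in the ``skipped`` attribute).
    """
    shared = meth_resid.columns.intersection(expr_resid.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    M = meth_resid[shared]
    E = expr_resid[shared]
    n = len(shared)
    X = M.reindex(pairs["probe_id"]).to_numpy(float)
    Y = E.reindex(pairs["transcript_id"]).to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    ok = sxx > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.einsum("ij,ij->i", Xc, Yc) / sxx
        rss = np.einsum("ij,ij->i", Yc, Yc) - slope**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # exact linear relations drive the t to infinity; report p = 0 there
    p = np.where(np.isfinite(t), p, np.where(ok, 0.0, np.nan))
    out = pairs.copy()
    out["coeff"] = np.where(ok, slope, np.nan)
    out["se"] = np.where(ok, se, np.nan)
    out["p_raw"] = np.where(ok, p, np.nan)
    out["p_fdr"] = adjust_pvalues(out["p_raw"].to_numpy(), "bh")
    out.attrs["skipped"] = pairs.loc[~ok, "probe_id"].tolist()
    return out


@dataclass
class EqtmResults:
    """Per-pair association table plus the pairing metadata."""

    pairs: pd.DataFrame  # probe_id, transcript_id, distance_bp, coeff, se, p_raw, p_fdr
    window: int
    n_samples: int

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.pairs[self.pairs["p_fdr"] < fdr]

    def summary(self) -> str:
        n_sig = int((self.pairs["p_fdr"] < 0.05).sum())
        return (
            f"eQTM: {len(self.pairs)} cis pairs tested within ±{self.window} bp "
            f"on {self.n_samples} samples; {n_sig} FDR-significant (5%)"
        )


class EqtmModel:
    """Cis eQTM model over a methylation dataset and an expression dataset.

    Parameters
    ----------
    dataset : MethylationDataset (or any object with .beta/.annotation/.samples)
    expression : ExpressionDataset
    candidates : iterable of candidate probe ids (defaults to all probes)
    window : cis window in bp around each CpG (boundary inclusive)
    cell_props : sample x k proportions for the covariate design
    batch_on_expression / batch_on_methylation : whether rna_batch enters the
        residualization on each side (expression yes / methylation no by
        default).
    """

    def __init__(self, dataset, expression, candidates=None,
                 window: int = 250_000, cell_props: pd.DataFrame | None = None,
                 batch_on_expression: bool = True,
                 batch_on_methylation: bool = False) -> None:
        self.dataset = dataset
        self.expression = expression
        self.candidates = (
            pd.Index(candidates) if candidates is not None else dataset.beta.index
        )
        self.window = window
        self.cell_props = cell_props
        self.batch_on_expression = batch_on_expression
        self.batch_on_methylation = batch_on_methylation

    def fit(self) -> EqtmResults:
        shared = self.dataset.beta.columns.intersection(
            self.expression.logcpm.columns
        )
        samples = self.dataset.samples.loc[shared]
        cp = self.cell_props.loc[shared] if self.cell_props is not None else None
        beta = self.dataset.beta.loc[
            self.candidates.intersection(self.dataset.beta.index), shared
        ]
        meth_design = build_covariate_design(
            samples, cp, include_batch=self.batch_on_methylation
        )
        expr_design = build_covariate_design(
            samples, cp, include_batch=self.batch_on_expression
        )
        meth_resid = residualize(beta, meth_design)
        expr_resid = residualize(self.expression.logcpm[shared], expr_design)
        pairs = pair_cis(
            self.dataset.annotation.loc[beta.index],
            self.expression.annotation,
            window=self.window,
        )
        table = associate_eqtm(pairs, meth_resid, expr_resid)
        return EqtmResults(pairs=table, window=self.window, n_samples=len(shared))
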