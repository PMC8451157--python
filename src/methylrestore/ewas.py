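"""Per-CpG robust-regression EWAS with empirical-Bayes variance moderation.

Each CpG is regressed on randomization group (never-smoker reference) plus
covariates (infant sex, gestational age, estimated cell proportions) by
Huber M-estimation.  Inference runs on the M scale (logit2 beta) with
limma-style variance shrinkage across probes; effect sizes are additionally
reported as Δβ from an unmoderated beta-scale fit of the same design.

Two contrasts are computed from the one fit:

* ``PN``: placebo smokers minus never-smokers (the smoking effect)
* ``VP``: vitamin-C smokers minus placebo smokers (the treatment effect)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import MethylationDataset
from .qc import beta_to_m

HUBER_C = 1.345
MAD_NORM = 0.6744897501960817  # Phi^-1(0.75)
CHI2_1_MEDIAN = 0.45493642311957174

CONTRASTS = {
    "PN": {"placebo": 1.0},                 # placebo - never (never = reference)
    "VP": {"vitc": 1.0, "placebo": -1.0},   # vitc - placebo
}


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, cell_props: pd.DataFrame | None = None,
                 extra_covariates: list[str] | None = None) -> pd.DataFrame:
    """Design matrix: intercept, group indicators (never = reference),
    infant sex, gestational age, and the leading k-1 cell-proportion columns
    (last dropped against the intercept)."""
    cols = {"intercept": np.ones(len(samples))}
    grp = samples["group"]
    cols["placebo"] = (grp == "placebo").astype(float).to_numpy()
    cols["vitc"] = (grp == "vitc").astype(float).to_numpy()
    if "infant_sex" in samples.columns:
        cols["sex_M"] = (samples["infant_sex"] == "M").astype(float).to_numpy()
    if "ga_weeks" in samples.columns:
        ga = samples["ga_weeks"].astype(float)
        cols["ga_weeks"] = (ga - ga.mean()).to_numpy()
    X = pd.DataFrame(cols, index=samples.index)
    if cell_props is not None:
        missing = samples.index.difference(cell_props.index)
        if len(missing):
            raise ValueError(
                f"cell proportions missing for sample(s) {missing[:5].tolist()}"
            )
        cp = cell_props.loc[samples.index]
        for c in cp.columns[:-1]:  # drop last column vs intercept
            X[f"prop_{c}"] = cp[c].astype(float).to_numpy()
    for c in extra_covariates or []:
        X[c] = pd.to_numeric(samples[c]).to_numpy()
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(f"design matrix is rank deficient; columns {list(X.columns)}")
    if arr.shape[0] <= arr.shape[1] + 2:
        raise ValueError("too few samples for the design (need n > p + 2)")
    return X


def contrast_vector(design_columns, contrast: str) -> np.ndarray:
    spec_ = CONTRASTS[contrast]
    c = np.zeros(len(design_columns))
    for name, w in spec_.items():
        c[list(design_columns).index(name)] = w
    return c


# ---------------------------------------------------------------------------
# Huber IRLS
# ---------------------------------------------------------------------------

def _huber_irls_matrix(Y: np.ndarray, X: np.ndarray, c: float = HUBER_C,
                       tol: float = 1e-8, max_iter: int = 50):
    """Row-wise Huber IRLS of every row of ``Y`` (probes x samples) on the
    shared design ``X`` (samples x p).

    Returns ``(B, cov_unscaled, s2, d, converged)`` where ``cov_unscaled`` is
    (X'X)^-1 (broadcast per probe), ``s2`` the Huber psi-corrected robust
    residual variance, and ``d = n - p``.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    n, p = X.shape
    P = Y.shape[0]
    d = n - p
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y.T).T  # OLS start
    converged = np.zeros(P, dtype=bool)
    W = np.ones_like(Y)
    for _ in range(max_iter):
        R = Y - B @ X.T
        absR = np.abs(R)
        scale = np.median(absR, axis=1) / MAD_NORM
        pure = scale < 1e-12  # interpolation-exact fits: keep unit weights
        thresh = c * np.where(pure, np.inf, scale)
        with np.errstate(invalid="ignore"):
            W = np.minimum(
                1.0, thresh[:, None] / np.where(absR > 0, absR, np.inf)
            )
        W[np.isnan(W)] = 1.0  # inf/inf on interpolation-exact rows
        XtWX = np.einsum("pn,ni,nj->pij", W, X, X, optimize=True)
        XtWy = np.einsum("pn,ni->pi", W * Y, X, optimize=True)
        try:
            B_new = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            B_new = np.stack(
                [np.linalg.lstsq(XtWX[i], XtWy[i], rcond=None)[0] for i in range(P)]
            )
        step = np.max(np.abs(B_new - B), axis=1)
        B = B_new
        converged |= step < tol
        if converged.all():
            break
    R = Y - B @ X.T
    # Huber robust variance: psi-based scale with the finite-sample
    # correction K^2 / (mean psi')^2 (Huber 1981, as in M-estimation SEs)
    scale = np.median(np.abs(R), axis=1) / MAD_NORM
    pure = scale < 1e-12
    safe_scale = np.where(pure, 1.0, scale)
    rs = R / safe_scale[:, None]
    psi = np.clip(rs, -c, c)
    psip = (np.abs(rs) <= c).astype(float)
    mean_psip = np.maximum(psip.mean(axis=1), 1e-12)
    K = 1.0 + (p / n) * psip.var(axis=1) / mean_psip**2
    s2 = (
        np.einsum("pn,pn->p", psi, psi) * safe_scale**2
        / max(d, 1) / mean_psip**2 * K**2
    )
    s2 = np.where(pure, 0.0, s2)
    # classical (X'X)^-1 with the psi-corrected s2: the weighting already
    # enters through psi, so the weighted form would double-discount
    cov_unscaled = np.broadcast_to(np.linalg.inv(XtX), (P, p, p)).copy()
    return B, cov_unscaled, s2, d, converged


def fit_probe_rlm(y: np.ndarray, X) -> tuple:
    """Huber IRLS fit of a single response vector.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) design matrix (DataFrame or array), full rank

    Returns
    -------
    (coef, se, s2, d); all-NaN coef/se if the fit failed to converge.
    """
    Xarr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    B, cov, s2, d, conv = _huber_irls_matrix(y[None, :], Xarr)
    if not conv[0]:
        p = Xarr.shape[1]
        return np.full(p, np.nan), np.full(p, np.nan), np.nan, d
    se = np.sqrt(np.diag(cov[0]) * s2[0])
    return B[0], se, float(s2[0]), d


# ---------------------------------------------------------------------------
# empirical-Bayes moderation (variance shrinkage across probes)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, monotone)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square prior on the
    residual variances (Smyth-style on log s^2).

    Returns (d0, s0_squared); d0 = inf when the observed spread of log s^2 is
    no larger than the chi-square sampling spread alone.
    """
    s2 = np.asarray(s2, float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 100:
        raise ValueError("need >= 100 probes with positive finite s2")
    e = np.log(s2[ok]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        # point-mass prior: no spread beyond chi-square sampling noise, so the
        # prior sits at the (geometric) mean of the observed variances; when
        # all s^2 coincide this reproduces the common value exactly
        return np.inf, float(np.exp(np.log(s2[ok]).mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def posterior_variance(s2: np.ndarray, d: int, d0: float, s0_sq: float) -> np.ndarray:
    """Shrunken variance (d0*s0^2 + d*s2) / (d0 + d); s0^2 when d0 = inf."""
    s2 = np.asarray(s2, float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + d * s2) / (d0 + d)


def ebayes_moderate(coef: np.ndarray, unscaled_se: np.ndarray, s2: np.ndarray,
                    d: int):
    """Moderated t statistics for one contrast across all probes.

    ``unscaled_se`` is sqrt(c' (X'WX)^-1 c), i.e. the standard error divided
    by the residual standard deviation.

    Returns dict with t, p, df_total, d0, s0_sq, s2_post.
    """
    d0, s0_sq = estimate_prior(s2, d)
    s2_post = posterior_variance(s2, d, d0, s0_sq)
    t = coef / (unscaled_se * np.sqrt(s2_post))
    df_total = d0 + d
    df_use = min(df_total, 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df_use)
    return {
        "t": t, "p": p, "df_total": df_total, "d0": d0,
        "s0_sq": s0_sq, "s2_post": s2_post,
    }


# ---------------------------------------------------------------------------
# multiple-testing adjustment / inflation
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: str = "bh", m: int | None = None) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment.

    NaN entries propagate as NaN and are excluded from the effective test
    count.  ``m`` overrides the test count (useful for worked arithmetic on a
    sub-table of a larger family).
    """
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m_eff = int(ok.sum()) if m is None else int(m)
    if m_eff == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(1.0, p[ok] * m_eff)
    elif method == "bh":
        pv = p[ok]
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m_eff / (np.arange(len(pv)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up monotone
        adj = np.empty_like(pv)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def genomic_inflation(p) -> float:
    """Inflation factor lambda: median observed 1-df chi-square over its
    null median (~0.4549)."""
    p = np.asarray(p, float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need >= 100 finite p-values")
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class EwasResults:
    """Per-CpG, per-contrast EWAS output.

    ``tables`` maps contrast name -> DataFrame (indexed by probe id) with
    columns chrom, pos, coef_m, se_m, coef_beta, se_beta, t_moderated,
    p_raw, p_bonferroni, p_bh.  ``d0``/``s0_sq`` are the moderation
    hyperparameters, ``s2``/``df_residual`` the per-fit variances.
    """

    tables: dict
    s2: pd.Series
    df_residual: int
    d0: float
    s0_sq: float
    design: pd.DataFrame

    def table(self, contrast: str) -> pd.DataFrame:
        return self.tables[contrast]

    @property
    def contrasts(self) -> list[str]:
        return list(self.tables)

    def pval_track(self, contrast: str) -> pd.DataFrame:
        """(chrom, pos, p_raw) sorted for DMR calling."""
        t = self.tables[contrast]
        return (
            t[["chrom", "pos", "p_raw"]]
            .dropna()
            .sort_values(["chrom", "pos"], kind="stable")
        )

    def summary(self) -> str:
        lines = [
            "EWAS results",
            f"  probes: {len(self.s2)}   residual df: {self.df_residual}",
            f"  moderation prior: d0 = {self.d0:.3g}, s0^2 = {self.s0_sq:.4g}",
        ]
        for name, t in self.tables.items():
            n_bonf = int((t["p_bonferroni"] < 0.05).sum())
            n_fdr = int((t["p_bh"] < 0.05).sum())
            n_nom = int((t["p_raw"] < 0.05).sum())
            lines.append(
                f"  contrast {name}: {n_nom} nominal, {n_fdr} FDR, "
                f"{n_bonf} Bonferroni significant CpGs"
            )
        return "\n".join(lines)


class EwasModel:
    """Three-group differential-methylation model for a
    :class:`MethylationDataset`.

    Parameters
    ----------
    dataset : MethylationDataset
    cell_props : optional sample x k proportion DataFrame used as covariates
        (leading k-1 columns enter the design).
    extra_covariates : extra numeric sample-sheet columns to adjust for.
    """

    def __init__(self, dataset: MethylationDataset,
                 cell_props: pd.DataFrame | None = None,
                 extra_covariates: list[str] | None = None) -> None:
        self.dataset = dataset
        if cell_props is not None:
            missing = dataset.sample_ids.difference(cell_props.index)
            if len(missing):
                raise ValueError(
                    f"sample ids absent from cell proportions: {missing[:5].tolist()}"
                )
        self.design = build_design(dataset.samples, cell_props, extra_covariates)

    def fit(self, scale: str = "both",
            contrasts: tuple[str, ...] = ("PN", "VP")) -> EwasResults:
        """Fit every probe and assemble per-contrast tables.

        ``scale`` selects which regressions run: "M", "beta", or "both".
        M-scale p-values carry the inference; beta-scale coefficients are the
        reported Δβ.  With a single scale the other scale's columns are NaN.
        """
        if scale not in {"M", "beta", "both"}:
            raise ValueError("scale must be 'M', 'beta' or 'both'")
        ds = self.dataset
        X = self.design.to_numpy(float)
        beta_mat = ds.beta.to_numpy(float)

        res_m = res_b = None
        if scale in ("M", "both"):
            res_m = _huber_irls_matrix(beta_to_m(beta_mat), X)
        if scale in ("beta", "both"):
            res_b = _huber_irls_matrix(beta_mat, X)

        ann = ds.annotation
        tables = {}
        d = X.shape[0] - X.shape[1]
        d0 = s0_sq = np.nan
        s2_series = pd.Series(np.nan, index=ds.probe_ids)
        for name in contrasts:
            cvec = contrast_vector(self.design.columns, name)
            cols: dict[str, np.ndarray] = {}
            if res_m is not None:
                B, cov, s2, d, conv = res_m
                coef = B @ cvec
                unscaled = np.sqrt(np.einsum("i,pij,j->p", cvec, cov, cvec))
                coef = np.where(conv, coef, np.nan)
                mod = ebayes_moderate(coef, unscaled, np.where(conv, s2, np.nan), d)
                d0, s0_sq = mod["d0"], mod["s0_sq"]
                s2_series = pd.Series(np.where(conv, s2, np.nan), index=ds.probe_ids)
                cols["coef_m"] = coef
                cols["se_m"] = unscaled * np.sqrt(s2)
                cols["t_moderated"] = mod["t"]
                cols["p_raw"] = np.where(conv, mod["p"], np.nan)
                cols["df_total"] = np.full(len(coef), mod["df_total"])
            if res_b is not None:
                Bb, covb, s2b, db, convb = res_b
                coef_b = Bb @ cvec
                se_b = np.sqrt(
                    np.einsum("i,pij,j->p", cvec, covb, cvec) * s2b
                )
                cols["coef_beta"] = np.where(convb, coef_b, np.nan)
                cols["se_beta"] = np.where(convb, se_b, np.nan)
                if res_m is None:  # beta-only fit: classical t inference
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t = coef_b / se_b
                    cols["p_raw"] = np.where(
                        convb, 2.0 * stats.t.sf(np.abs(t), db), np.nan
                    )
            p_raw = cols["p_raw"]
            cols["p_bonferroni"] = adjust_pvalues(p_raw, "bonferroni")
            cols["p_bh"] = adjust_pvalues(p_raw, "bh")
            table = pd.DataFrame(cols, index=ds.probe_ids)
            table.insert(0, "chrom", ann["chrom"])
            table.insert(1, "pos", ann["pos"])
            tables[name] = table.sort_values(["chrom", "pos"], kind="stable")
        return EwasResults(
            tables=tables, s2=s2_series, df_residual=d,
            d0=float(d0), s0_sq=float(s0_sq), design=self.design,
        )


def run_ewas(dataset: MethylationDataset, cell_props: pd.DataFrame | None = None,
             scale: str = "both",
             contrasts: tuple[str, ...] = ("PN", "VP"),
             extra_covariates: list[str] | None = None) -> EwasResults:
    """Functional wrapper: build the design and fit both contrasts."""
    return EwasModel(dataset, cell_props, extra_covariates).fit(scale, contrasts)
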