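"""Reference-free cell-mixture deconvolution of methylation beta values.

The beta matrix is factorized as ``beta ~ mu @ omega.T`` where ``mu`` holds
per-cell-type methylation profiles (entries in [0, 1]) and each sample's
``omega`` row is a point on the probability simplex.  Fitting alternates

* an exact simplex-constrained least-squares solve for each sample's
  proportions (active-set enumeration over the <= 2^k - 1 faces, vectorized
  across samples), and
* an ordinary least-squares update of the profiles, clipped to [0, 1],

until the squared-error deviance stabilizes.  The number of components is
selected by bootstrap cross-validation: fit on a bootstrap resample of
samples, freeze the profiles and the per-probe residual variances, then
re-estimate proportions for the held-out samples and score their Gaussian
deviance ``log(sigma2_p) + r^2 / sigma2_p`` per entry; the k with minimal
mean held-out deviance wins, ties resolved downward.  The variance term is
what penalizes superfluous components: an overfit k understates the
training variances and the held-out ratio term grows, whereas a plain
squared-error score decreases (weakly) in k and cannot select a minimum.

Factorization runs on the beta scale, where a cell mixture is genuinely
linear.  Only the leading k-1 proportion columns should enter a downstream
regression design (the last is collinear with the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def select_top_variable(beta: pd.DataFrame, n: int = 10_000) -> list:
    """The ``n`` probes with the largest across-sample variance; exact ties
    broken by probe-id lexicographic order."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > beta.shape[0]:
        raise ValueError(f"n = {n} exceeds probe count {beta.shape[0]}")
    var = beta.var(axis=1, ddof=1)
    ranked = var.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[:n].tolist()


def _simplex_lsq(mu: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact solve of min ||mu w - b||^2 s.t. w >= 0, sum w = 1, for every
    column b of B (probes x samples).  Enumerate support sets; each candidate
    solves the equality-constrained KKT system on its face, infeasible
    candidates are discarded, and the feasible candidate with the smallest
    objective is the global optimum.
    """
    P, k = mu.shape
    N = B.shape[1]
    G = mu.T @ mu                      # k x k
    C = mu.T @ B                       # k x N
    best_obj = np.full(N, np.inf)
    best_w = np.zeros((k, N))
    for size in range(1, k + 1):
        for S in combinations(range(k), size):
            S = list(S)
            m = len(S)
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = G[np.ix_(S, S)]
            A[:m, m] = 1.0
            A[m, :m] = 1.0
            rhs = np.vstack([C[S, :], np.ones((1, N))])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            w_S = sol[:m, :]
            feasible = (w_S >= -1e-12).all(axis=0)
            if not feasible.any():
                continue
            # objective up to the constant ||b||^2
            obj = np.einsum("in,ij,jn->n", w_S, G[np.ix_(S, S)], w_S) \
                - 2.0 * np.einsum("in,in->n", C[S, :], w_S)
            better = feasible & (obj < best_obj - 1e-15)
            if better.any():
                best_obj[better] = obj[better]
                best_w[:, better] = 0.0
                W_full = np.zeros((k, better.sum()))
                W_full[S, :] = np.clip(w_S[:, better], 0.0, None)
                best_w[:, better] = W_full
    # renormalize away active-set clipping drift (<= 1e-12)
    best_w /= best_w.sum(axis=0, keepdims=True)
    return best_w.T                    # samples x k


@dataclass
class CellMixtureResults:
    """Fitted mixture: profiles, proportions and the deviance trace."""

    k: int
    mu: pd.DataFrame       # probe x k
    omega: pd.DataFrame    # sample x k, simplex rows
    deviance: float
    n_iter: int
    converged: bool

    def summary(self) -> str:
        mean_props = self.omega.mean(axis=0)
        lines = [
            f"Cell-mixture deconvolution (k = {self.k})",
            f"  deviance: {self.deviance:.6g}  iterations: {self.n_iter}"
            f"  converged: {self.converged}",
            "  mean proportions: "
            + ", ".join(f"{c}={v:.3f}" for c, v in mean_props.items()),
        ]
        return "\n".join(lines)

    def design_columns(self) -> pd.DataFrame:
        """Leading k-1 proportion columns for use as regression covariates."""
        return self.omega.iloc[:, :-1]


class CellMixtureModel:
    """Reference-free deconvolution model over a beta matrix.

    Parameters
    ----------
    beta : probe x sample DataFrame (typically the top-variable subset).
    seed : controls k-means initialization and any bootstrap.
    """

    def __init__(self, beta: pd.DataFrame, seed: int = 0) -> None:
        self.beta = beta
        self.seed = seed

    def fit(self, k: int, tol: float = 1e-6, max_iter: int = 100,
            mu_init: np.ndarray | None = None) -> CellMixtureResults:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k >= self.beta.shape[1]:
            raise ValueError(f"k = {k} must be < n_samples = {self.beta.shape[1]}")
        B = self.beta.to_numpy(float)
        P, N = B.shape
        if mu_init is None:
            if k == 1:
                mu = B.mean(axis=1, keepdims=True)
            else:
                km = KMeans(n_clusters=k, n_init=10,
                            random_state=self.seed % (2**31))
                labels = km.fit_predict(B.T)
                mu = np.stack(
                    [B[:, labels == j].mean(axis=1) if (labels == j).any()
                     else B.mean(axis=1) for j in range(k)], axis=1
                )
        else:
            mu = np.asarray(mu_init, float).copy()
        prev = np.inf
        dev = np.inf
        n_iter = 0
        converged = False
        omega = np.full((N, k), 1.0 / k)
        for n_iter in range(1, max_iter + 1):
            omega = _simplex_lsq(mu, B)
            # profiles: per-probe least squares against the proportions
            OtO = omega.T @ omega
            try:
                mu = np.linalg.solve(OtO, omega.T @ B.T).T
            except np.linalg.LinAlgError:
                mu = (np.linalg.pinv(OtO) @ (omega.T @ B.T)).T
            mu = np.clip(mu, 0.0, 1.0)
            dev = float(np.sum((B - mu @ omega.T) ** 2))
            if prev < np.inf and abs(prev - dev) <= tol * max(prev, 1e-300):
                converged = True
                break
            prev = dev
        cols = [f"cell_{j+1}" for j in range(k)]
        return CellMixtureResults(
            k=k,
            mu=pd.DataFrame(mu, index=self.beta.index, columns=cols),
            omega=pd.DataFrame(omega, index=self.beta.columns, columns=cols),
            deviance=dev,
            n_iter=n_iter,
            converged=converged,
        )

    def heldout_deviance(self, mu: np.ndarray, sigma2: np.ndarray,
                         B_out: np.ndarray) -> float:
        """Mean per-entry Gaussian deviance of held-out samples with
        profiles and per-probe variances frozen (proportions re-estimated
        on the held-out samples)."""
        sigma2 = np.maximum(np.asarray(sigma2, float), 1e-12)
        omega = _simplex_lsq(mu, B_out)
        resid = B_out - mu @ omega.T
        return float(np.mean(np.log(sigma2)[:, None] + resid**2 / sigma2[:, None]))

    def choose_k(self, k_range=range(1, 6), n_boot: int = 20,
                 tol: float = 1e-6, max_iter: int = 100) -> int:
        """Bootstrap-cross-validated component count.

        For each k and each bootstrap resample of samples: fit on the
        resample, freeze mu and the per-probe residual variances, score the
        mean per-entry Gaussian deviance on the samples not drawn (with
        proportions re-estimated).  Returns the k with minimal mean
        held-out deviance; ties go to the smaller k.
        """
        ks = list(k_range)
        if not ks:
            raise ValueError("k_range is empty")
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        B = self.beta.to_numpy(float)
        N = B.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7919]))
        scores = {k: [] for k in ks}
        for b in range(n_boot):
            idx = rng.integers(0, N, size=N)
            oob = np.setdiff1d(np.arange(N), np.unique(idx))
            if len(oob) == 0:
                continue
            boot_beta = self.beta.iloc[:, idx]
            boot_beta.columns = [f"b{j}" for j in range(N)]
            sub = CellMixtureModel(boot_beta, seed=self.seed + 1000 + b)
            B_boot = boot_beta.to_numpy(float)
            for k in ks:
                fit = sub.fit(k, tol=tol, max_iter=max_iter)
                mu = fit.mu.to_numpy()
                resid = B_boot - mu @ fit.omega.to_numpy().T
                sigma2 = np.mean(resid**2, axis=1)
                scores[k].append(
                    self.heldout_deviance(mu, sigma2, B[:, oob])
                )
        mean_scores = {k: float(np.mean(v)) for k, v in scores.items()}
        best = min(sorted(ks), key=lambda k: (mean_scores[k], k))
        return best


def fit_mixture(beta: pd.DataFrame, k: int, seed: int = 0) -> CellMixtureResults:
    """Functional wrapper around :meth:`CellMixtureModel.fit`."""
    return CellMixtureModel(beta, seed=seed).fit(k)


def choose_k(beta: pd.DataFrame, k_range=range(1, 6), n_boot: int = 20,
             seed: int = 0) -> int:
    """Functional wrapper around :meth:`CellMixtureModel.choose_k`."""
    return CellMixtureModel(beta, seed=seed).choose_k(k_range, n_boot)


def align_components(estimated: pd.DataFrame, truth: pd.DataFrame):
    """Best column permutation matching estimated proportions to truth;
    returns (permuted estimate, mean absolute error)."""
    from itertools import permutations

    est = estimated.to_numpy(float)
    tru = truth.to_numpy(float)
    k = est.shape[1]
    best_perm, best_mae = None, np.inf
    for perm in permutations(range(k)):
        mae = float(np.mean(np.abs(est[:, perm] - tru)))
        if mae < best_mae:
            best_mae, best_perm = mae, perm
    aligned = estimated.iloc[:, list(best_perm)]
    aligned.columns = truth.columns
    return aligned, best_mae
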