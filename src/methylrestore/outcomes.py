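"""Association of candidate CpGs with infant lung function (FEF75) and
composite wheeze at 12 months, in the smoker-offspring (RCT) samples only.

FEF75 is modelled by Huber robust linear regression of the outcome on the
CpG beta value plus infant length at PFT, infant sex and gestational age;
wheeze by logistic regression on the same design (a robust
linear-probability variant is available behind a flag).  P-values are
BH-FDR adjusted within the candidate set; the nominal p < 0.05 flag is also
reported, the convention for small candidate panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import MethylationDataset, OutcomeTable
from .ewas import adjust_pvalues, fit_probe_rlm
from scipy import stats


def composite_wheeze(report, dx, meds):
    """OR of the three wheeze components with missing handling: any true ->
    true; all missing -> missing; otherwise false (a missing component among
    observed negatives counts as a negative response).

    Accepts scalars (bool or None/NaN) or aligned pandas Series.
    """
    if isinstance(report, pd.Series):
        df = pd.concat([report, dx, meds], axis=1)
        any_true = df.eq(True).any(axis=1)
        all_missing = df.isna().all(axis=1)
        out = pd.Series(False, index=df.index, dtype=object)
        out[any_true] = True
        out[all_missing] = np.nan
        return out

    vals = [report, dx, meds]
    is_missing = [v is None or (isinstance(v, float) and np.isnan(v)) for v in vals]
    if any(v is True for v in vals):
        return True
    if all(is_missing):
        return np.nan
    return False


def _outcome_design(outcomes: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(outcomes)),
            "length_at_pft_cm": outcomes["length_at_pft_cm"].astype(float)
            - outcomes["length_at_pft_cm"].astype(float).mean(),
            "sex_M": (outcomes["infant_sex"] == "M").astype(float),
            "ga_weeks": outcomes["ga_weeks"].astype(float)
            - outcomes["ga_weeks"].astype(float).mean(),
        },
        index=outcomes.index,
    )
    return X


def associate_outcome(candidates, dataset: MethylationDataset,
                      outcomes: OutcomeTable | pd.DataFrame,
                      outcome: str = "fef75",
                      wheeze_linear: bool = False) -> pd.DataFrame:
    """Per-CpG association of the candidate probes with one outcome.

    Only samples present in the outcome table (the smoker offspring) are
    used.  Returns a table with coeff, se, p_raw, p_fdr (BH within the
    candidate set), nominal_significant and n_used per probe.
    """
    out_df = outcomes.data if isinstance(outcomes, OutcomeTable) else outcomes
    if outcome not in {"fef75", "wheeze"}:
        raise ValueError("outcome must be 'fef75' or 'wheeze'")
    samples = dataset.sample_ids.intersection(out_df.index)
    if len(samples) == 0:
        raise ValueError("no overlap between methylation samples and outcomes")
    candidates = pd.Index(candidates)
    missing = candidates.difference(dataset.probe_ids)
    if len(missing):
        raise ValueError(
            f"candidate probes absent from dataset: {missing[:5].tolist()}"
        )
    out_sub = out_df.loc[samples]
    if outcome == "fef75":
        y_all = out_sub["fef75"].astype(float)
    else:
        y_all = out_sub["composite_wheeze"]
    keep = y_all.notna()
    out_sub = out_sub[keep]
    y = y_all[keep]
    X0 = _outcome_design(out_sub)
    beta = dataset.beta.loc[candidates, out_sub.index]

    rows = []
    yv = y.to_numpy(float) if outcome == "fef75" else y.astype(float).to_numpy()
    for pid in candidates:
        x = beta.loc[pid].to_numpy(float)
        X = np.column_stack([X0.to_numpy(float), x])
        coeff = se = p = np.nan
        if outcome == "fef75" or wheeze_linear:
            try:
                b, s, s2, d = fit_probe_rlm(yv, X)
                coeff, se = b[-1], s[-1]
                if np.isfinite(coeff) and se > 0:
                    p = 2.0 * stats.t.sf(abs(coeff / se), d)
            except (ValueError, np.linalg.LinAlgError):
                pass
        else:
            try:
                fit = sm.GLM(yv, X, family=sm.families.Binomial()).fit(maxiter=100)
                coeff, se = fit.params[-1], fit.bse[-1]
                p = fit.pvalues[-1]
                if not np.isfinite(se) or se > 1e4:  # separation
                    coeff = se = p = np.nan
            except Exception:
                pass
        rows.append((pid, coeff, se, p))
    table = pd.DataFrame(
        rows, columns=["probe_id", "coeff", "se", "p_raw"]
    ).set_index("probe_id")
    table["p_fdr"] = adjust_pvalues(table["p_raw"].to_numpy(), "bh")
    table["nominal_significant"] = table["p_raw"] < 0.05
    table["outcome"] = outcome
    table["n_used"] = len(out_sub)
    return table


@dataclass
class OutcomeResults:
    tables: dict  # outcome -> per-probe table

    def table(self, outcome: str) -> pd.DataFrame:
        return self.tables[outcome]

    def summary(self) -> str:
        lines = ["Candidate CpG / infant-outcome associations"]
        for name, t in self.tables.items():
            lines.append(
                f"  {name}: {int(t['nominal_significant'].sum())} nominal, "
                f"{int((t['p_fdr'] < 0.05).sum())} FDR significant of "
                f"{len(t)} candidates (n = {t['n_used'].iloc[0] if len(t) else 0})"
            )
        return "\n".join(lines)


class OutcomeModel:
    """Candidate-CpG outcome model over the smoker-offspring samples."""

    def __init__(self, dataset: MethylationDataset, outcomes,
                 candidates, wheeze_linear: bool = False) -> None:
        self.dataset = dataset
        self.outcomes = outcomes
        self.candidates = pd.Index(candidates)
        self.wheeze_linear = wheeze_linear

    def fit(self, outcome_names=("fef75", "wheeze")) -> OutcomeResults:
        tables = {
            name: associate_outcome(
                self.candidates, self.dataset, self.outcomes, name,
                wheeze_linear=self.wheeze_linear,
            )
            for name in outcome_names
        }
        return OutcomeResults(tables=tables)
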