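"""Probe-level quality control and the beta <-> M transforms.

Probes are excluded by the standard Infinium-array rules: non-CpG probes,
probes with a beadcount < 3 in at least 5% of samples, SNP-overlapping
probes, probes with detection p > 0.01 in one or more samples,
cross-hybridizing probes, and probes on the sex chromosomes.  Inference
downstream runs on the M scale (logit2 of the beta value); effect sizes are
reported on the beta scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MethylationDataset

#: order in which exclusion rules claim a probe for attribution purposes
RULE_ORDER = (
    "noncpg",
    "beadcount",
    "snp",
    "detection_p",
    "crossreactive",
    "sex_chromosome",
)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class RawProbeSet:
    """Unfiltered probe set: betas plus the QC side-channels.

    All matrices share probe (row) and sample (column) ordering.  Beadcount
    entries may be NaN (absent), which is treated as failing the beadcount
    rule.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    beadcount: pd.DataFrame
    flags: pd.DataFrame  # columns: flag_noncpg, flag_snp, flag_crossreactive
    chrom: pd.Series

    def __post_init__(self) -> None:
        idx = self.beta.index
        cols = self.beta.columns
        for name in ("detection_p", "beadcount"):
            m = getattr(self, name)
            if not (m.index.equals(idx) and m.columns.equals(cols)):
                raise ValueError(f"{name} matrix not aligned with beta matrix")
        if not self.flags.index.equals(idx) or not self.chrom.index.equals(idx):
            raise ValueError("flags/chrom not aligned with beta matrix")


@dataclass
class FilterReport:
    """Book-keeping of which probes each rule removed."""

    removed_by_rule: dict  # rule -> list of probe ids (first-match attribution)
    match_sets: dict       # rule -> list of probe ids (full match set)
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removed_by_rule": {k: list(v) for k, v in self.removed_by_rule.items()},
            "removed_counts": {k: len(v) for k, v in self.removed_by_rule.items()},
            "match_sets": {k: list(v) for k, v in self.match_sets.items()},
        }


def beta_to_m(beta, eps: float = 0.001):
    """logit2 transform: M = log2(b / (1 - b)) with b clipped to [eps, 1-eps].

    Parameters
    ----------
    beta : scalar or array-like in [0, 1]
    eps : clip bound in (0, 0.5); prevents infinities at 0 and 1.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        return type(beta)(m, index=beta.index, **(
            {"columns": beta.columns} if isinstance(beta, pd.DataFrame) else {}
        ))
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^m / (1 + 2^m)."""
    arr = np.asarray(m, dtype=float)
    # expit(log(2) * m) is numerically stable for large |m|
    from scipy.special import expit

    b = expit(np.log(2.0) * arr)
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(b)
    if isinstance(m, (pd.DataFrame, pd.Series)):
        return type(m)(b, index=m.index, **(
            {"columns": m.columns} if isinstance(m, pd.DataFrame) else {}
        ))
    return b


def _rule_masks(raw: RawProbeSet, beadcount_min: int = 3,
                beadcount_frac: float = 0.05, detection_alpha: float = 0.01) -> dict:
    n_samples = raw.beta.shape[1]
    bead = raw.beadcount.to_numpy(dtype=float)
    bead_fail = np.isnan(bead) | (bead < beadcount_min)
    masks = {
        "noncpg": raw.flags["flag_noncpg"].to_numpy(bool),
        # "at least 5% of samples": fraction >= 0.05 exactly
        "beadcount": bead_fail.sum(axis=1) / n_samples >= beadcount_frac,
        "snp": raw.flags["flag_snp"].to_numpy(bool),
        "detection_p": (raw.detection_p.to_numpy(float) > detection_alpha).any(axis=1),
        "crossreactive": raw.flags["flag_crossreactive"].to_numpy(bool),
        "sex_chromosome": raw.chrom.isin(SEX_CHROMS).to_numpy(),
    }
    return masks


def filter_probes(raw: RawProbeSet, annotation: pd.DataFrame | None = None,
                  samples: pd.DataFrame | None = None) -> tuple:
    """Apply the exclusion rules, returning the retained dataset and a report.

    A probe is removed iff it matches at least one rule; the report attributes
    each removal to the first matching rule (in :data:`RULE_ORDER`) and also
    records the full per-rule match sets.  Rule order therefore never changes
    WHICH probes survive, only the attribution.

    Parameters
    ----------
    raw : RawProbeSet
    annotation : optional probe annotation to carry into the output dataset;
        a minimal one (chrom + flags) is synthesized when absent.
    samples : optional sample sheet; a bare one is synthesized when absent.
    """
    if raw.beta.size == 0:
        raise ValueError("empty beta matrix")
    vals = raw.beta.to_numpy(float)
    nonfinite = ~np.isfinite(vals)
    if nonfinite.any():
        bad = raw.beta.index[nonfinite.any(axis=1)]
        raise ValueError(f"non-finite beta values at probe(s) {bad[:5].tolist()}")

    masks = _rule_masks(raw)
    probe_ids = raw.beta.index
    claimed = np.zeros(len(probe_ids), dtype=bool)
    removed_by_rule, match_sets = {}, {}
    for rule in RULE_ORDER:
        mask = masks[rule]
        match_sets[rule] = probe_ids[mask].tolist()
        first = mask & ~claimed
        removed_by_rule[rule] = probe_ids[first].tolist()
        claimed |= mask

    keep = ~claimed
    report = FilterReport(
        removed_by_rule=removed_by_rule,
        match_sets=match_sets,
        n_input=len(probe_ids),
        n_retained=int(keep.sum()),
    )

    kept_ids = probe_ids[keep]
    if annotation is None:
        annotation = pd.DataFrame(
            {
                "chrom": raw.chrom,
                "pos": np.arange(1, len(probe_ids) + 1),
                "strand": "+",
            },
            index=probe_ids,
        ).join(raw.flags)
    if samples is None:
        samples = pd.DataFrame(index=raw.beta.columns)
    dataset = MethylationDataset(
        beta=raw.beta.loc[kept_ids],
        annotation=annotation.loc[kept_ids],
        samples=samples.loc[raw.beta.columns],
    )
    return dataset, report
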