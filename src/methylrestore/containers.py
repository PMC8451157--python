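"""Core in-memory containers shared by all pipeline stages.

The central object is :class:`MethylationDataset`, a beta-value matrix with
aligned probe annotation and sample sheet.  Expression and outcome data get
thin wrappers that enforce the same alignment rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("never", "placebo", "vitc")

ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "flag_snp",
    "flag_crossreactive",
    "flag_noncpg",
    "island_region",
]


@dataclass
class MethylationDataset:
    """Probe x sample beta matrix plus probe annotation and sample sheet.

    Parameters
    ----------
    beta : pandas.DataFrame
        Rows are probe ids, columns are sample ids, entries in [0, 1].
    annotation : pandas.DataFrame
        Indexed by probe id; carries ``chrom``, ``pos`` (1-based), ``strand``,
        probe-type flags and the CpG-island region class.
    samples : pandas.DataFrame
        Indexed by sample id; carries ``group`` in {never, placebo, vitc},
        ``infant_sex`` in {M, F}, ``ga_weeks`` and any extra covariates.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            dup = self.beta.index[self.beta.index.duplicated()].tolist()
            raise ValueError(f"duplicated probe ids: {dup[:5]}")
        if self.beta.columns.duplicated().any():
            dup = self.beta.columns[self.beta.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dup[:5]}")
        missing = self.beta.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} probes missing annotation, e.g. {missing[:5].tolist()}"
            )
        missing_s = self.beta.columns.difference(self.samples.index)
        if len(missing_s):
            raise ValueError(
                f"{len(missing_s)} samples missing from sample sheet, e.g. "
                f"{missing_s[:5].tolist()}"
            )
        if "group" in self.samples.columns:
            bad = set(self.samples["group"].dropna()) - set(VALID_GROUPS)
            if bad:
                raise ValueError(
                    f"unknown group label(s) {sorted(bad)}; allowed: {list(VALID_GROUPS)}"
                )
        # keep annotation/sample sheet aligned to the matrix
        self.annotation = self.annotation.loc[self.beta.index]
        self.samples = self.samples.loc[self.beta.columns]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        return MethylationDataset(
            beta=self.beta.loc[probe_ids],
            annotation=self.annotation.loc[probe_ids],
            samples=self.samples,
        )

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        return MethylationDataset(
            beta=self.beta[list(sample_ids)],
            annotation=self.annotation,
            samples=self.samples.loc[list(sample_ids)],
        )


@dataclass
class ExpressionDataset:
    """Transcript x sample log-CPM matrix with a TSS annotation table.

    ``annotation`` is indexed by transcript id with columns ``gene_name``,
    ``chrom``, ``tss_pos`` (1-based) and ``strand``.  Samples must be a subset
    of the methylation samples; sample covariates (incl. ``rna_batch``) live
    in ``samples``.
    """

    logcpm: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.logcpm.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} transcripts missing annotation, e.g. "
                f"{missing[:5].tolist()}"
            )
        self.annotation = self.annotation.loc[self.logcpm.index]
        self.samples = self.samples.loc[self.logcpm.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.logcpm.columns


@dataclass
class OutcomeTable:
    """Infant-outcome table, one row per (smoker-offspring) sample.

    Columns: ``fef75`` (mL/s), the three wheeze components
    (``wheeze_report``, ``wheeze_dx``, ``wheeze_meds``), ``composite_wheeze``,
    ``length_at_pft_cm``, ``infant_sex``, ``ga_weeks``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicated sample ids in outcome table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index
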