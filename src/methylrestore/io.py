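"""Readers and writers for the pipeline's plain-text formats.

All writers emit a deterministic column order and full-precision floats, so
a write -> read round trip reproduces values exactly and identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MethylationDataset, ExpressionDataset, OutcomeTable, VALID_GROUPS,
)

SAMPLE_SHEET_COLUMNS = [
    "group", "infant_sex", "ga_weeks", "length_at_pft_cm", "rna_batch",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()].tolist()
        raise ValueError(f"duplicated {what}: {dup[:5]}")


def read_beta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index.name = "probe_id"
    _check_unique(df.index, "probe ids")
    _check_unique(df.columns, "sample ids")
    return df


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "sample_id"
    _check_unique(df.index, "sample ids")
    if "group" in df.columns:
        bad = set(df["group"].dropna()) - set(VALID_GROUPS)
        if bad:
            raise ValueError(
                f"unknown group label(s) {sorted(bad)}; allowed: {list(VALID_GROUPS)}"
            )
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_SHEET_COLUMNS if c in samples.columns]
    cols += [c for c in samples.columns if c not in cols]
    samples[cols].to_csv(path, index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    _check_unique(df.index, "probe ids")
    for col in ("flag_snp", "flag_crossreactive", "flag_noncpg"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "transcript_id"
    _check_unique(df.index, "transcript ids")
    return df


def write_tss_table(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", index_label="transcript_id")


def read_outcomes(path) -> OutcomeTable:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "sample_id"
    for col in ("wheeze_report", "wheeze_dx", "wheeze_meds", "composite_wheeze"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return OutcomeTable(df)


def write_outcomes(outcomes: OutcomeTable, path) -> None:
    outcomes.data.to_csv(path, index_label="sample_id")


def write_results_tsv(table: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_results_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(dmrs, path, name_of=None) -> None:
    """BED6+ export of DMR records, sorted by (chrom, start).

    score = -log10 p_sidak (capped at 1000), strand = '.'; extra columns:
    n_probes, p_sidak.
    """
    recs = sorted(dmrs, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        for i, r in enumerate(recs):
            name = name_of(r) if name_of else f"dmr_{i+1}"
            score = min(1000.0, -np.log10(max(r.p_sidak, 1e-300)))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score:.2f}\t.\t"
                f"{r.n_probes}\t{r.p_sidak:.6g}\n"
            )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_dataset(meth: MethylationDataset, outdir,
                  expression: ExpressionDataset | None = None,
                  outcomes: OutcomeTable | None = None,
                  truth=None) -> dict:
    """Write a full synthetic study to a directory; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "samples": outdir / "samples.csv",
        "annotation": outdir / "annotation.tsv",
    }
    write_beta_tsv(meth.beta, paths["beta"])
    write_sample_sheet(meth.samples, paths["samples"])
    write_annotation(meth.annotation, paths["annotation"])
    if expression is not None:
        paths["expression"] = outdir / "expression.tsv"
        paths["tss"] = outdir / "tss.tsv"
        expression.logcpm.to_csv(paths["expression"], sep="\t",
                                 index_label="transcript_id")
        write_tss_table(expression.annotation, paths["tss"])
    if outcomes is not None:
        paths["outcomes"] = outdir / "outcomes.csv"
        write_outcomes(outcomes, paths["outcomes"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        write_json(truth.to_json_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_dataset(indir) -> MethylationDataset:
    indir = Path(indir)
    return MethylationDataset(
        beta=read_beta_tsv(indir / "beta.tsv"),
        annotation=read_annotation(indir / "annotation.tsv"),
        samples=read_sample_sheet(indir / "samples.csv"),
    )


def read_expression(indir, samples: pd.DataFrame) -> ExpressionDataset:
    indir = Path(indir)
    logcpm = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
    logcpm.index.name = "transcript_id"
    return ExpressionDataset(
        logcpm=logcpm,
        annotation=read_tss_table(indir / "tss.tsv"),
        samples=samples.loc[logcpm.columns],
    )
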