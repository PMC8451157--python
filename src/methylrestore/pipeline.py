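"""End-to-end pipeline: QC -> deconvolution -> EWAS -> DMR calling ->
restoration selection -> eQTM -> infant outcomes, with a machine-readable
run manifest.  Stages are resumable: when ``resume`` is set and a stage's
outputs already exist they are reloaded instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .combp import call_dmrs, dmr_table
from .containers import MethylationDataset
from .decon import CellMixtureModel, select_top_variable
from .ewas import EwasModel
from .outcomes import OutcomeModel
from .qc import RawProbeSet, filter_probes
from .restore import restored_dmr_table, restored_dmrs, select_candidates

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "k_cell_types": None,         # None -> bootstrap selection
    "decon_top_n": 10_000,
    "decon_k_range": [1, 2, 3, 4],
    "decon_n_boot": 10,
    "dmr_seed": 0.05,
    "dmr_dist": 500,
    "dmr_bin_size": 50,
    "dmr_sidak_alpha": 0.05,
    "eqtm_window": 250_000,
    "fdr": 0.05,
    "resume": False,
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    for key in ("input_dir", "output_dir"):
        if key not in cfg:
            raise ValueError(f"config must set {key!r}")
    return cfg


def _param_hash(cfg: dict) -> str:
    payload = json.dumps(
        {k: v for k, v in sorted(cfg.items())
         if k not in ("resume", "input_dir", "output_dir")},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(manifest: dict, name: str):
    """Context manager recording stage success/failure in the manifest."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"].setdefault(name, {"status": "ok"})
            return False

    return _Ctx()


def run_pipeline(config) -> dict:
    """Execute all stages; ``config`` is a dict or a YAML path.

    Returns the manifest dict (also written to ``output_dir/manifest.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else {
        **DEFAULT_CONFIG, **config
    }
    for key in ("input_dir", "output_dir"):
        if key not in cfg:
            raise ValueError(f"config must set {key!r}")
    indir = Path(cfg["input_dir"])
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    resume = bool(cfg.get("resume"))
    manifest = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "param_hash": _param_hash(cfg),
        "stages": {},
    }

    # ------------------------------------------------------------------ qc
    with _stage(manifest, "qc"):
        dataset = mio.read_dataset(indir)
        have_artifacts = (indir / "detection_p.tsv").exists() and (
            indir / "beadcount.tsv"
        ).exists()
        if have_artifacts:
            detection_p = pd.read_csv(indir / "detection_p.tsv", sep="\t", index_col=0)
            beadcount = pd.read_csv(indir / "beadcount.tsv", sep="\t", index_col=0)
            flags = dataset.annotation[
                ["flag_noncpg", "flag_snp", "flag_crossreactive"]
            ]
            chrom = dataset.annotation["chrom"]
            flags_path = indir / "qc_flags.tsv"
            if flags_path.exists():
                extra = pd.read_csv(flags_path, sep="\t", index_col=0)
                flags = extra[["flag_noncpg", "flag_snp", "flag_crossreactive"]]
                chrom = extra["chrom"]
            raw = RawProbeSet(
                beta=dataset.beta, detection_p=detection_p,
                beadcount=beadcount, flags=flags, chrom=chrom,
            )
            dataset, report = filter_probes(
                raw, annotation=dataset.annotation, samples=dataset.samples
            )
            mio.write_json(report.to_dict(), outdir / "filter_report.json")
            mio.write_beta_tsv(dataset.beta, outdir / "beta_filtered.tsv")
            manifest["stages"]["qc"] = {
                "status": "ok", "n_retained": report.n_retained,
                "n_removed": report.n_removed,
            }
        else:
            manifest["stages"]["qc"] = {
                "status": "skipped", "reason": "no detection/beadcount artifacts",
            }

    # --------------------------------------------------------------- decon
    with _stage(manifest, "deconvolution"):
        props_path = outdir / "cell_proportions.csv"
        if resume and props_path.exists():
            cell_props = pd.read_csv(props_path, index_col=0)
            manifest["stages"]["deconvolution"] = {
                "status": "resumed", "k": cell_props.shape[1],
            }
        else:
            top = select_top_variable(
                dataset.beta, min(cfg["decon_top_n"], dataset.n_probes)
            )
            model = CellMixtureModel(dataset.beta.loc[top], seed=cfg["seed"])
            k = cfg.get("k_cell_types")
            if k is None:
                k = model.choose_k(cfg["decon_k_range"], cfg["decon_n_boot"])
            fit = model.fit(int(k))
            cell_props = fit.omega
            cell_props.to_csv(props_path, index_label="sample_id")
            manifest["stages"]["deconvolution"] = {
                "status": "ok", "k": int(k), "deviance": fit.deviance,
            }

    # ---------------------------------------------------------------- ewas
    with _stage(manifest, "ewas"):
        ewas_res = EwasModel(dataset, cell_props).fit(scale="both")
        for name, t in ewas_res.tables.items():
            mio.write_results_tsv(t, outdir / f"ewas_{name}.tsv")
        manifest["stages"]["ewas"] = {
            "status": "ok",
            "d0": ewas_res.d0, "s0_sq": ewas_res.s0_sq,
            "n_probes": int(len(ewas_res.s2)),
        }

    # ----------------------------------------------------------------- dmr
    dmrs = {}
    with _stage(manifest, "dmr"):
        for name in ewas_res.contrasts:
            sig, all_recs = call_dmrs(
                ewas_res, name,
                seed=cfg["dmr_seed"], dist=cfg["dmr_dist"],
                bin_size=cfg["dmr_bin_size"],
                sidak_alpha=cfg["dmr_sidak_alpha"],
            )
            dmrs[name] = sig
            mio.write_bed(sig, outdir / f"dmrs_{name}.bed")
            mio.write_results_tsv(
                dmr_table(all_recs), outdir / f"dmrs_{name}_all.tsv",
                index_label="region_idx",
            )
        manifest["stages"]["dmr"] = {
            "status": "ok",
            "n_significant": {k: len(v) for k, v in dmrs.items()},
        }

    # --------------------------------------------------------- restoration
    with _stage(manifest, "restoration"):
        candidates, audit = select_candidates(
            ewas_res.table("PN"), ewas_res.table("VP"), alpha=cfg["alpha"]
        )
        mio.write_results_tsv(candidates, outdir / "restored_candidates.tsv")
        mio.write_results_tsv(audit, outdir / "restoration_audit.tsv")
        pairs = restored_dmrs(
            dmrs.get("VP", []), dmrs.get("PN", []),
            delta_beta_vp=ewas_res.table("VP")["coef_beta"],
            delta_beta_pn=ewas_res.table("PN")["coef_beta"],
        )
        mio.write_results_tsv(
            restored_dmr_table(pairs), outdir / "restored_dmrs.tsv",
            index_label="pair_idx",
        )
        manifest["stages"]["restoration"] = {
            "status": "ok",
            "n_overlap": int(len(audit)),
            "n_restored": int(len(candidates)),
            "n_restored_dmrs": len(pairs),
        }

    # ---------------------------------------------------------------- eqtm
    with _stage(manifest, "eqtm"):
        if (indir / "expression.tsv").exists():
            from .eqtm import EqtmModel

            expr = mio.read_expression(indir, dataset.samples)
            universe = set(candidates.index)
            for rec in dmrs.get("VP", []):
                universe.update(rec.probe_ids)
            pn = ewas_res.table("PN")
            universe.update(pn.index[pn["p_bh"] < cfg["fdr"]])
            universe = sorted(universe & set(dataset.probe_ids))
            eqtm_res = EqtmModel(
                dataset, expr, candidates=universe,
                window=cfg["eqtm_window"], cell_props=cell_props,
            ).fit()
            mio.write_results_tsv(
                eqtm_res.pairs, outdir / "eqtm_pairs.tsv", index_label="pair_idx"
            )
            manifest["stages"]["eqtm"] = {
                "status": "ok",
                "n_candidates": len(universe),
                "n_pairs": int(len(eqtm_res.pairs)),
                "n_fdr_significant": int(
                    (eqtm_res.pairs["p_fdr"] < cfg["fdr"]).sum()
                ),
            }
        else:
            manifest["stages"]["eqtm"] = {
                "status": "skipped", "reason": "no expression inputs",
            }

    # ------------------------------------------------------------ outcomes
    with _stage(manifest, "outcomes"):
        if (indir / "outcomes.csv").exists() and len(candidates):
            out_tab = mio.read_outcomes(indir / "outcomes.csv")
            res = OutcomeModel(dataset, out_tab, candidates.index).fit()
            for name, t in res.tables.items():
                mio.write_results_tsv(t, outdir / f"outcomes_{name}.tsv")
            manifest["stages"]["outcomes"] = {
                "status": "ok",
                "n_nominal": {
                    name: int(t["nominal_significant"].sum())
                    for name, t in res.tables.items()
                },
            }
        else:
            manifest["stages"]["outcomes"] = {
                "status": "skipped",
                "reason": "no outcome table or no candidates",
            }

    mio.write_json(manifest, outdir / "manifest.json")
    return manifest
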