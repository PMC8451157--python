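"""Seeded synthetic-data generator emulating a three-group placental
methylation study (never-smoker / placebo smoker / vitamin-C smoker).

The generator produces every input the analysis pipeline consumes — a
beta-value matrix, sample sheet, probe and transcript annotation, a log-CPM
expression matrix, and an infant-outcome table — together with ground-truth
labels for parameter-recovery tests.

Generative model
----------------
* Baseline methylation is a convex mixture of ``k_true`` latent cell-type
  profiles (probe x k matrix ``mu``) with per-sample simplex proportions
  ``omega`` drawn from a Dirichlet.
* Smoking-affected CpGs shift the placebo group by a signed delta on the
  beta scale (hypomethylation more likely, as observed for maternal smoking).
  A fraction of those CpGs is "restored": the vitamin-C group shifts back
  toward never-smoker levels (treatment delta opposite in sign to the
  smoking delta); the remainder shift further in the smoking direction.
* Per-cell-type profiles are bimodal (mostly near 0 or 1, a minority
  intermediate), with a set of cell-type-discriminating CpGs at opposite
  extremes, mirroring real arrays and anchoring the reference-free
  deconvolution.  Gaussian noise is added on the M scale (logit2), then
  mapped back, so betas stay in (0, 1).
* A set of probe clusters with < 500 bp inter-probe spacing carries shared
  smoking + restoration effects: these are the true differentially
  methylated regions.  All remaining probes are > 1000 bp apart.
* Expression for truly coupled CpG-transcript pairs is linear in the CpG's
  beta residual; infant FEF75 and composite wheeze load on a latent
  "methylation damage" factor shared by the designated outcome CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylationDataset, ExpressionDataset, OutcomeTable
from .qc import beta_to_m, m_to_beta

_CHROMS = ("chr1", "chr2", "chr3")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design
    (24 never-smokers, 35 placebo, 37 vitamin C; smoking |Δβ| of a few
    percent with ~95% of affected CpGs partially restored)."""

    seed: int = 0
    n_never: int = 24
    n_placebo: int = 35
    n_vitc: int = 37
    n_probes: int = 20_000
    n_smoking_cpgs: int = 400
    frac_restored: float = 0.95
    delta_beta_smoking: float = 0.05
    restore_fraction_mean: float = 0.8
    n_dmr_clusters: int = 25
    noise_sd_m: float = 0.25
    k_true: int = 2
    n_transcripts: int = 300
    n_eqtm_pairs: int = 40
    eqtm_slope: float = -3.4
    expr_noise_sd: float = 0.11
    n_outcome_cpgs: int = 50
    outcome_slope: float = 250.0  # marginal FEF75 change (mL/s) per unit beta

    def __post_init__(self) -> None:
        counts = dict(
            n_never=self.n_never, n_placebo=self.n_placebo, n_vitc=self.n_vitc,
            n_probes=self.n_probes, n_transcripts=self.n_transcripts,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("n_never", "n_placebo", "n_vitc"):
            if getattr(self, name) < 3:
                raise ValueError(
                    f"{name} < 3: per-group regression downstream is unidentifiable"
                )
        if not 0.0 <= self.frac_restored <= 1.0:
            raise ValueError("frac_restored must be in [0, 1]")
        if self.n_smoking_cpgs > 0 and not 0.0 < self.delta_beta_smoking < 0.5:
            raise ValueError("delta_beta_smoking must be in (0, 0.5)")
        if not 0.0 < self.restore_fraction_mean <= 1.0:
            raise ValueError("restore_fraction_mean must be in (0, 1]")
        if self.n_smoking_cpgs > self.n_probes:
            raise ValueError("n_smoking_cpgs exceeds n_probes")

    @property
    def n_samples(self) -> int:
        return self.n_never + self.n_placebo + self.n_vitc


@dataclass
class SyntheticTruth:
    """Ground-truth labels for recovery tests."""

    smoking_cpgs: dict          # probe_id -> signed true delta_beta_PN
    restored_cpgs: dict         # probe_id -> signed true delta_beta_VP
    true_cell_profiles: pd.DataFrame   # probe x k, entries in [0, 1]
    true_cell_proportions: pd.DataFrame  # sample x k, rows on the simplex
    eqtm_truth: list            # (probe_id, transcript_id, slope)
    outcome_truth: list         # (probe_id, outcome_name, marginal slope)
    dmr_truth: list             # dicts: chrom, start, end (1-based inclusive)

    def to_json_dict(self) -> dict:
        return {
            "smoking_cpgs": self.smoking_cpgs,
            "restored_cpgs": self.restored_cpgs,
            "eqtm_truth": [list(t) for t in self.eqtm_truth],
            "outcome_truth": [list(t) for t in self.outcome_truth],
            "dmr_truth": self.dmr_truth,
        }


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Deterministic substream derived from the one global seed."""
    digest = sum(ord(c) * 131**i for i, c in enumerate(stream)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, digest]))


def _positions(config: SimulationConfig, rng: np.random.Generator):
    """Assign probes to 3 chromosomes; plant DMR clusters (3-10 probes,
    spacing < 500 bp), all other consecutive probes > 1000 bp apart."""
    n = config.n_probes
    cluster_sizes = rng.integers(3, 11, size=config.n_dmr_clusters)
    if cluster_sizes.sum() > n:
        raise ValueError("n_dmr_clusters too large for n_probes")
    chrom_of = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    cluster_members: list[np.ndarray] = []
    per_chrom = np.full(len(_CHROMS), n // len(_CHROMS))
    per_chrom[: n % len(_CHROMS)] += 1
    cluster_chrom = np.arange(config.n_dmr_clusters) % len(_CHROMS)
    idx = 0
    for ci, n_chrom in enumerate(per_chrom):
        cur = int(rng.integers(10_000, 50_000))
        my_clusters = list(cluster_sizes[cluster_chrom == ci])
        remaining = int(n_chrom) - int(np.sum(my_clusters))
        if remaining < 0:
            raise ValueError("cluster probes exceed chromosome capacity")
        n_slots = len(my_clusters) + remaining
        cluster_slots = (
            set(rng.choice(n_slots, size=len(my_clusters), replace=False).tolist())
            if my_clusters
            else set()
        )
        cl_iter = iter(my_clusters)
        for slot in range(n_slots):
            if slot in cluster_slots:
                size = int(next(cl_iter))
                members = []
                for j in range(size):
                    chrom_of[idx] = _CHROMS[ci]
                    pos[idx] = cur
                    members.append(idx)
                    if j < size - 1:
                        cur += int(rng.integers(50, 450))
                    idx += 1
                cluster_members.append(np.array(members))
                cur += int(1001 + rng.exponential(2000))
            else:
                chrom_of[idx] = _CHROMS[ci]
                pos[idx] = cur
                idx += 1
                cur += int(1001 + rng.exponential(2000))
    assert idx == n
    return chrom_of, pos, cluster_members


def generate_dataset(config: SimulationConfig):
    """Generate the full synthetic study.

    Returns
    -------
    (MethylationDataset, ExpressionDataset, OutcomeTable, SyntheticTruth)
    """
    n = config.n_probes
    n_samples = config.n_samples
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample_id")
    group = np.array(
        ["never"] * config.n_never
        + ["placebo"] * config.n_placebo
        + ["vitc"] * config.n_vitc
    )

    # --- genomic layout -------------------------------------------------
    rng_pos = _rng(config, "positions")
    chrom_of, pos, cluster_members = _positions(config, rng_pos)

    # --- cell-mixture baseline -----------------------------------------
    rng_cell = _rng(config, "cells")
    k = config.k_true
    cluster_probe_idx = (
        np.concatenate(cluster_members) if cluster_members else np.array([], int)
    )
    # per-probe methylation state, bimodal as on real arrays: mostly
    # unmethylated or methylated in every cell type, a minority intermediate
    state = rng_cell.choice(3, size=n, p=[0.4, 0.4, 0.2])  # 0 low, 1 high, 2 mid
    state[cluster_probe_idx] = 2  # planted regions live at variable CpGs
    low = rng_cell.uniform(0.02, 0.07, size=(n, k))
    high = rng_cell.uniform(0.93, 0.98, size=(n, k))
    mid = np.clip(
        rng_cell.uniform(0.2, 0.8, size=n)[:, None]
        + rng_cell.normal(0.0, 0.05, size=(n, k)),
        0.05, 0.95,
    )
    mu = np.where(state[:, None] == 0, low,
                  np.where(state[:, None] == 1, high, mid))
    # cell-type-discriminating CpGs (opposite extremes) anchor the simplex
    # and make the reference-free factorization identifiable
    extreme = np.setdiff1d(np.flatnonzero(state != 2), cluster_probe_idx)
    n_disc = min(max(n // 10, 0), len(extreme))
    disc = rng_cell.choice(extreme, size=n_disc, replace=False)
    if k > 1 and n_disc:
        split = rng_cell.integers(1, k, size=n_disc)  # low component count
        lo_disc = rng_cell.uniform(0.02, 0.06, size=(n_disc, k))
        hi_disc = rng_cell.uniform(0.94, 0.98, size=(n_disc, k))
        which_low = np.arange(k)[None, :] < split[:, None]
        perm = np.argsort(rng_cell.random((n_disc, k)), axis=1)
        which_low = np.take_along_axis(which_low, perm, axis=1)
        mu[disc] = np.where(which_low, lo_disc, hi_disc)
    alpha = np.linspace(4.0, 2.0, k) if k > 1 else np.array([1.0])
    omega = rng_cell.dirichlet(alpha, size=n_samples)  # sample x k
    beta_base = mu @ omega.T  # probe x sample

    # --- smoking + restoration effects ---------------------------------
    rng_eff = _rng(config, "effects")
    n_cluster = len(cluster_probe_idx)
    n_extra = max(config.n_smoking_cpgs - n_cluster, 0)
    # effects go on intermediate CpGs (where a beta shift has headroom),
    # matching the variable CpGs where smoking effects are observed
    taken = np.union1d(cluster_probe_idx, disc)
    available = np.setdiff1d(np.flatnonzero(state == 2), taken)
    if n_extra > len(available):
        available = np.concatenate(
            [available, np.setdiff1d(np.arange(n), np.union1d(taken, available))]
        )
    extra = rng_eff.choice(available, size=min(n_extra, len(available)), replace=False)
    smoking_idx = np.concatenate([cluster_probe_idx, extra]).astype(int)

    delta_pn = np.zeros(n)
    delta_vp = np.zeros(n)
    if len(smoking_idx) and config.n_smoking_cpgs > 0:
        mag = rng_eff.gamma(4.0, config.delta_beta_smoking / 4.0, size=len(smoking_idx))
        mag = np.clip(mag, 0.02, 0.45)
        # maternal smoking mostly hypomethylates
        sign = np.where(rng_eff.random(len(smoking_idx)) < 0.82, -1.0, 1.0)
        restored_flag = rng_eff.random(len(smoking_idx)) < config.frac_restored
        # shared sign/magnitude/restoration status within a planted cluster
        offset = 0
        for members in cluster_members:
            m = len(members)
            sign[offset : offset + m] = sign[offset]
            mag[offset : offset + m] = mag[offset]
            restored_flag[offset : offset + m] = restored_flag[offset]
            offset += m
        a = config.restore_fraction_mean
        rfrac = rng_eff.beta(8.0 * a, max(8.0 * (1.0 - a), 1e-6), size=len(smoking_idx))
        rfrac = np.clip(rfrac, 0.05, 1.0)
        d_pn = sign * mag
        # restored: treatment reverses the smoking shift; otherwise it
        # pushes further in the smoking direction
        d_vp = np.where(restored_flag, -rfrac * d_pn, rfrac * d_pn)
        delta_pn[smoking_idx] = d_pn
        delta_vp[smoking_idx] = d_vp

    beta_true = beta_base.copy()
    is_placebo = group == "placebo"
    is_vitc = group == "vitc"
    beta_true[:, is_placebo] += delta_pn[:, None]
    beta_true[:, is_vitc] += (delta_pn + delta_vp)[:, None]
    beta_true = np.clip(beta_true, 0.001, 0.999)

    rng_noise = _rng(config, "noise")
    m_vals = beta_to_m(beta_true) + rng_noise.normal(
        0.0, config.noise_sd_m, size=beta_true.shape
    )
    beta_obs = m_to_beta(m_vals)

    beta_df = pd.DataFrame(beta_obs, index=probe_ids, columns=sample_ids)

    # --- sample sheet ---------------------------------------------------
    rng_cov = _rng(config, "covariates")
    infant_sex = rng_cov.choice(["M", "F"], size=n_samples)
    ga_weeks = np.round(rng_cov.normal(39.0, 1.0, size=n_samples), 1)
    length_at_pft = np.round(rng_cov.normal(75.0, 3.0, size=n_samples), 1)
    rna_batch = rng_cov.choice(["B1", "B2"], size=n_samples)
    samples = pd.DataFrame(
        {
            "group": group,
            "infant_sex": infant_sex,
            "ga_weeks": ga_weeks,
            "length_at_pft_cm": length_at_pft,
            "rna_batch": rna_batch,
        },
        index=sample_ids,
    )

    annotation = pd.DataFrame(
        {
            "chrom": chrom_of,
            "pos": pos,
            "strand": "+",
            "flag_snp": False,
            "flag_crossreactive": False,
            "flag_noncpg": False,
            "island_region": rng_cov.choice(
                ["island", "shore", "shelf", "opensea"], size=n,
                p=[0.3, 0.25, 0.1, 0.35],
            ),
        },
        index=probe_ids,
    )

    meth = MethylationDataset(beta=beta_df, annotation=annotation, samples=samples)

    # --- expression -----------------------------------------------------
    rng_expr = _rng(config, "expression")
    # RNA-seq available for a subset of samples (emulates 71 of 96)
    n_rna = {"never": 18, "placebo": 26, "vitc": 27}
    rna_samples = []
    for g, cnt in n_rna.items():
        members = sample_ids[group == g]
        cnt = min(cnt, len(members))
        rna_samples.extend(rng_expr.choice(members, size=cnt, replace=False).tolist())
    rna_samples = pd.Index(sorted(rna_samples))

    tx_ids = pd.Index(
        [f"ENST{i:07d}" for i in range(config.n_transcripts)], name="transcript_id"
    )
    n_pairs = min(config.n_eqtm_pairs, config.n_transcripts, n)
    # coupled CpGs are intermediate-methylation probes (expression tracks a
    # CpG only where methylation actually varies), preferring the
    # smoking-affected set so the restored CpGs are the eQTM candidates
    mid_pool = np.flatnonzero(state == 2)
    preferred = np.intersect1d(mid_pool, smoking_idx)
    rest = np.setdiff1d(mid_pool, smoking_idx)
    if len(preferred) + len(rest) < n_pairs:
        rest = np.union1d(rest, np.setdiff1d(np.arange(n), preferred))
    # take at least half from the preferred set, more if rest is short
    take_pref = min(len(preferred), max(n_pairs // 2, n_pairs - len(rest)))
    chosen_pref = rng_expr.choice(preferred, size=take_pref, replace=False) \
        if take_pref else np.array([], int)
    chosen_rest = rng_expr.choice(rest, size=n_pairs - take_pref, replace=False)
    pair_probes = np.concatenate([chosen_pref, chosen_rest]).astype(int)
    tx_chrom = np.empty(config.n_transcripts, dtype=object)
    tx_pos = np.empty(config.n_transcripts, dtype=np.int64)
    # coupled transcripts sit within the cis window of their probe
    for j in range(n_pairs):
        p = pair_probes[j]
        tx_chrom[j] = chrom_of[p]
        tx_pos[j] = max(1, pos[p] + int(rng_expr.integers(-200_000, 200_001)))
    for j in range(n_pairs, config.n_transcripts):
        ci = int(rng_expr.integers(0, len(_CHROMS)))
        tx_chrom[j] = _CHROMS[ci]
        tx_pos[j] = int(rng_expr.integers(10_000, 30_000_000))
    tx_ann = pd.DataFrame(
        {
            "gene_name": [f"GENE{i}" for i in range(config.n_transcripts)],
            "chrom": tx_chrom,
            "tss_pos": tx_pos,
            "strand": rng_expr.choice(["+", "-"], size=config.n_transcripts),
        },
        index=tx_ids,
    )

    rna_mask = sample_ids.isin(rna_samples)
    sex_num = (infant_sex == "M").astype(float)
    batch_num = (rna_batch == "B2").astype(float)
    base_expr = rng_expr.normal(5.0, 1.5, size=config.n_transcripts)
    logcpm = (
        base_expr[:, None]
        + 0.3 * sex_num[None, rna_mask]
        + 0.05 * (ga_weeks[None, rna_mask] - 39.0)
        + 0.4 * batch_num[None, rna_mask]
        + rng_expr.normal(
            0.0, config.expr_noise_sd,
            size=(config.n_transcripts, int(rna_mask.sum())),
        )
    )
    eqtm_truth = []
    rna_cols = sample_ids[rna_mask]
    for j in range(n_pairs):
        p = pair_probes[j]
        b = beta_obs[p, rna_mask]
        logcpm[j] += config.eqtm_slope * (b - b.mean())
        eqtm_truth.append((probe_ids[p], tx_ids[j], config.eqtm_slope))
    expr_df = pd.DataFrame(logcpm, index=tx_ids, columns=rna_cols)
    expr = ExpressionDataset(
        logcpm=expr_df, annotation=tx_ann, samples=samples.loc[rna_cols]
    )

    # --- infant outcomes (smoker offspring only) ------------------------
    rng_out = _rng(config, "outcomes")
    smoker_mask = is_placebo | is_vitc
    smoker_ids = sample_ids[smoker_mask]
    n_smoker = len(smoker_ids)
    lam, sig_b = 0.05, 0.045  # factor loading / residual beta sd on beta scale
    z = rng_out.normal(0.0, 1.0, size=n_smoker)
    outcome_idx = rng_out.choice(
        np.setdiff1d(np.arange(n), smoking_idx),
        size=min(config.n_outcome_cpgs, n - len(smoking_idx)),
        replace=False,
    )
    # outcome CpGs load on the latent damage factor (beta scale)
    beta_df.loc[probe_ids[outcome_idx], smoker_ids] = np.clip(
        beta_df.loc[probe_ids[outcome_idx], smoker_ids].to_numpy()
        + lam * z[None, :],
        0.001, 0.999,
    )
    # marginal slope per unit beta = gamma * lam / (lam^2 + sig_b^2)
    gamma = config.outcome_slope * (lam**2 + sig_b**2) / lam
    fef75 = (
        200.0
        + gamma * z
        + 2.0 * (length_at_pft[smoker_mask] - 75.0)
        + 10.0 * sex_num[smoker_mask]
        + 5.0 * (ga_weeks[smoker_mask] - 39.0)
        + rng_out.normal(0.0, 0.5 * abs(gamma) + 1e-9, size=n_smoker)
    )
    logit_w = -0.5 - 0.9 * z  # lower latent factor -> more wheeze
    p_w = 1.0 / (1.0 + np.exp(-logit_w))
    composite = rng_out.random(n_smoker) < p_w
    report = composite & (rng_out.random(n_smoker) < 0.7)
    dx = composite & (rng_out.random(n_smoker) < 0.5)
    meds = composite & (rng_out.random(n_smoker) < 0.4)
    none_pos = composite & ~(report | dx | meds)
    report = report | none_pos  # composite true must have >= 1 positive item
    outcomes = OutcomeTable(
        pd.DataFrame(
            {
                "fef75": np.round(fef75, 2),
                "wheeze_report": report,
                "wheeze_dx": dx,
                "wheeze_meds": meds,
                "composite_wheeze": report | dx | meds,
                "length_at_pft_cm": length_at_pft[smoker_mask],
                "infant_sex": infant_sex[smoker_mask],
                "ga_weeks": ga_weeks[smoker_mask],
            },
            index=smoker_ids,
        )
    )

    dmr_truth = [
        {
            "chrom": str(chrom_of[members[0]]),
            "start": int(pos[members[0]]),
            "end": int(pos[members[-1]]),
        }
        for members in cluster_members
    ]
    truth = SyntheticTruth(
        smoking_cpgs={probe_ids[i]: float(delta_pn[i]) for i in smoking_idx},
        restored_cpgs={
            probe_ids[i]: float(delta_vp[i])
            for i in smoking_idx
            if delta_vp[i] != 0 and np.sign(delta_vp[i]) == -np.sign(delta_pn[i])
        },
        true_cell_profiles=pd.DataFrame(
            mu, index=probe_ids, columns=[f"cell_{j+1}" for j in range(k)]
        ),
        true_cell_proportions=pd.DataFrame(
            omega, index=sample_ids, columns=[f"cell_{j+1}" for j in range(k)]
        ),
        eqtm_truth=eqtm_truth,
        outcome_truth=[
            (probe_ids[i], "fef75", config.outcome_slope) for i in outcome_idx
        ],
        dmr_truth=dmr_truth,
    )
    return meth, expr, outcomes, truth


def generate_detection_artifacts(
    config: SimulationConfig,
    dataset: MethylationDataset,
    n_fail_per_rule: dict | None = None,
    fraction_fail: float = 0.0,
):
    """Detection-p / beadcount / flag artifacts with planted QC failures.

    Each planted probe fails exactly one rule; the returned truth series maps
    planted probe id -> rule name.  ``n_fail_per_rule`` keys follow
    :data:`methylrestore.qc.RULE_ORDER`; alternatively ``fraction_fail``
    splits a probe fraction evenly across the six rules.

    Returns
    -------
    (detection_p, beadcount, flags_with_chrom, truth)
    """
    from .qc import RULE_ORDER

    rng = _rng(config, "qc_artifacts")
    probe_ids = dataset.probe_ids
    sample_ids = dataset.sample_ids
    n, s = len(probe_ids), len(sample_ids)

    if n_fail_per_rule is None:
        per = int(round(fraction_fail * n / len(RULE_ORDER)))
        n_fail_per_rule = {rule: per for rule in RULE_ORDER}
    total = sum(n_fail_per_rule.values())
    if total > n:
        raise ValueError("more planted failures than probes")

    detection_p = pd.DataFrame(
        rng.uniform(0.0, 0.009, size=(n, s)), index=probe_ids, columns=sample_ids
    )
    beadcount = pd.DataFrame(
        rng.integers(5, 25, size=(n, s)), index=probe_ids, columns=sample_ids
    )
    flags = pd.DataFrame(
        {
            "flag_noncpg": False,
            "flag_snp": False,
            "flag_crossreactive": False,
            "chrom": dataset.annotation["chrom"].astype(object),
        },
        index=probe_ids,
    )

    chosen = rng.choice(n, size=total, replace=False)
    truth = {}
    off = 0
    min_bead_fail = int(np.ceil(0.05 * s))
    for rule in RULE_ORDER:
        cnt = n_fail_per_rule.get(rule, 0)
        for i in chosen[off : off + cnt]:
            pid = probe_ids[i]
            truth[pid] = rule
            if rule == "noncpg":
                flags.loc[pid, "flag_noncpg"] = True
            elif rule == "snp":
                flags.loc[pid, "flag_snp"] = True
            elif rule == "crossreactive":
                flags.loc[pid, "flag_crossreactive"] = True
            elif rule == "beadcount":
                cols = rng.choice(s, size=min_bead_fail, replace=False)
                beadcount.iloc[i, cols] = 2
            elif rule == "detection_p":
                col = int(rng.integers(0, s))
                detection_p.iloc[i, col] = float(rng.uniform(0.011, 0.5))
            elif rule == "sex_chromosome":
                flags.loc[pid, "chrom"] = "chrX"
        off += cnt
    return detection_p, beadcount, flags, pd.Series(truth, dtype=object)
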