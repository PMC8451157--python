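"""eQTM: residualization, cis pairing, association."""

import numpy as np
import pandas as pd
import pytest

from methylrestore.eqtm import (
    EqtmModel, associate_eqtm, build_covariate_design, pair_cis, residualize,
)


def _matrix(n_rows=20, n_samples=30, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        r.normal(size=(n_rows, n_samples)),
        index=[f"f{i}" for i in range(n_rows)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )


class TestResidualize:
    def test_intercept_only_centers(self):
        m = _matrix()
        cov = pd.DataFrame({"intercept": 1.0}, index=m.columns)
        res = residualize(m, cov)
        expect = m.sub(m.mean(axis=1), axis=0)
        assert np.allclose(res.to_numpy(), expect.to_numpy(), atol=1e-12)

    def test_exact_linear_zero_residuals(self):
        r = np.random.default_rng(1)
        cov = pd.DataFrame({"intercept": 1.0, "x": r.normal(size=30)},
                           index=[f"S{j:03d}" for j in range(30)])
        m = pd.DataFrame(
            np.outer([1.0, -2.0, 0.5], cov["x"].to_numpy()) + 3.0,
            index=["a", "b", "c"], columns=cov.index,
        )
        res = residualize(m, cov)
        assert np.max(np.abs(res.to_numpy())) < 1e-10

    def test_orthogonality(self):
        m = _matrix(seed=2)
        r = np.random.default_rng(3)
        cov = pd.DataFrame(
            {"intercept": 1.0, "x1": r.normal(size=30), "x2": r.normal(size=30)},
            index=m.columns,
        )
        res = residualize(m, cov)
        for col in cov.columns:
            x = cov[col].to_numpy()
            for i in range(len(m)):
                rr = res.iloc[i].to_numpy()
                assert abs(rr @ x) < 1e-8 * max(
                    np.linalg.norm(rr) * np.linalg.norm(x), 1e-12
                )

    def test_rank_deficient_names_columns(self):
        m = _matrix()
        r = np.random.default_rng(4)
        x = r.normal(size=30)
        cov = pd.DataFrame({"intercept": 1.0, "x1": x, "x1_dup": x},
                           index=m.columns)
        with pytest.raises(ValueError, match="collinear"):
            residualize(m, cov)


class TestPairCis:
    def _annotations(self):
        probes = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "pos": [1_000_000, 5_000_000, 100]},
            index=["cgA", "cgB", "cgC"],
        )
        tx = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr3"],
             "tss_pos": [1_250_000, 1_250_001, 100]},
            index=["t1", "t2", "t3"],
        )
        return probes, tx

    def test_boundary_inclusive(self):
        probes, tx = self._annotations()
        pairs = pair_cis(probes, tx, window=250_000)
        got = set(zip(pairs["probe_id"], pairs["transcript_id"]))
        assert ("cgA", "t1") in got      # exactly 250 kb
        assert ("cgA", "t2") not in got  # 250 kb + 1
        assert not any(p == "cgC" for p, _ in got)  # chromosome mismatch

    def test_matches_brute_force(self):
        r = np.random.default_rng(5)
        chroms = ["chr1", "chr2", "chr3"]
        probes = pd.DataFrame({
            "chrom": r.choice(chroms, 500),
            "pos": r.integers(1, 3_000_000, 500),
        }, index=[f"cg{i:08d}" for i in range(500)])
        tx = pd.DataFrame({
            "chrom": r.choice(chroms, 300),
            "tss_pos": r.integers(1, 3_000_000, 300),
        }, index=[f"t{i}" for i in range(300)])
        pairs = pair_cis(probes, tx, window=250_000)
        got = set(zip(pairs["probe_id"], pairs["transcript_id"]))
        brute = {
            (p, t)
            for p in probes.index for t in tx.index
            if probes.loc[p, "chrom"] == tx.loc[t, "chrom"]
            and abs(int(tx.loc[t, "tss_pos"]) - int(probes.loc[p, "pos"]))
            <= 250_000
        }
        assert got == brute
        # distance column is exact
        for _, row in pairs.iterrows():
            assert row["distance_bp"] == abs(
                int(tx.loc[row["transcript_id"], "tss_pos"])
                - int(probes.loc[row["probe_id"], "pos"])
            )


class TestAssociate:
    def test_exact_linear_relation(self):
        r = np.random.default_rng(6)
        x = r.normal(size=40)
        meth = pd.DataFrame([x], index=["cgA"],
                            columns=[f"S{j:03d}" for j in range(40)])
        expr = pd.DataFrame([2.5 * x], index=["t1"], columns=meth.columns)
        pairs = pd.DataFrame({"probe_id": ["cgA"], "transcript_id": ["t1"],
                              "distance_bp": [10]})
        out = associate_eqtm(pairs, meth, expr)
        assert out["coeff"].iloc[0] == pytest.approx(2.5, rel=1e-10)
        assert out["p_raw"].iloc[0] < 1e-30

    def test_zero_variance_skipped(self):
        meth = pd.DataFrame([[0.0] * 40], index=["cgA"],
                            columns=[f"S{j:03d}" for j in range(40)])
        expr = pd.DataFrame([np.random.default_rng(7).normal(size=40)],
                            index=["t1"], columns=meth.columns)
        pairs = pd.DataFrame({"probe_id": ["cgA"], "transcript_id": ["t1"],
                              "distance_bp": [10]})
        out = associate_eqtm(pairs, meth, expr)
        assert np.isnan(out["coeff"].iloc[0])
        assert out.attrs["skipped"] == ["cgA"]

    def test_fdr_monotone(self):
        r = np.random.default_rng(8)
        meth = _matrix(30, 50, seed=9)
        expr = _matrix(30, 50, seed=10)
        pairs = pd.DataFrame({
            "probe_id": r.choice(meth.index, 60),
            "transcript_id": r.choice(expr.index, 60),
            "distance_bp": 0,
        })
        out = associate_eqtm(pairs, meth, expr)
        sig = out[out["p_fdr"] < 0.05]
        assert (sig["p_raw"] < 0.05).all()
        assert (out["p_fdr"] >= out["p_raw"] - 1e-15).all()


class TestEqtmModel:
    def test_planted_slopes_recovered(self, small_study):
        truth = small_study["truth"]
        cand = [p for p, _, _ in truth.eqtm_truth]
        res = EqtmModel(
            small_study["meth"], small_study["expr"], candidates=cand,
            cell_props=truth.true_cell_proportions,
        ).fit()
        tp = {(p, t): s for p, t, s in truth.eqtm_truth}
        hits = res.pairs[[
            (a, b) in tp
            for a, b in zip(res.pairs["probe_id"], res.pairs["transcript_id"])
        ]]
        assert len(hits) == len(tp)
        within = np.abs(hits["coeff"] - [tp[(a, b)] for a, b in
                                         zip(hits["probe_id"],
                                             hits["transcript_id"])])
        assert (within <= 3 * hits["se"]).mean() >= 0.9
        assert (hits["p_fdr"] < 0.05).mean() >= 0.9

    def test_covariate_span_invariance(self, small_study):
        """Adding a covariate-spanned component to expression leaves the
        association statistics unchanged."""
        truth = small_study["truth"]
        cand = [p for p, _, _ in truth.eqtm_truth][:10]
        expr = small_study["expr"]
        base = EqtmModel(small_study["meth"], expr, candidates=cand,
                         cell_props=truth.true_cell_proportions).fit()
        samples = expr.samples
        shift = 5.0 * (samples["infant_sex"] == "M").astype(float).to_numpy()
        bumped_logcpm = expr.logcpm.add(
            pd.Series(shift, index=samples.index), axis=1
        )
        bumped = type(expr)(logcpm=bumped_logcpm, annotation=expr.annotation,
                            samples=expr.samples)
        alt = EqtmModel(small_study["meth"], bumped, candidates=cand,
                        cell_props=truth.true_cell_proportions).fit()
        assert np.allclose(base.pairs["coeff"], alt.pairs["coeff"],
                           atol=1e-8, equal_nan=True)

    def test_batch_design(self, small_study):
        X = build_covariate_design(small_study["expr"].samples,
                                   include_batch=True)
        assert any(c.startswith("batch_") for c in X.columns)
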