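"""comb-p stages: ACF, Stouffer-Liptak, smoothing, regions, Sidak."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylrestore.combp import (
    AcfEstimate, DmrRecord, estimate_acf, find_regions, make_track,
    score_region, sidak_correct, slk_smooth, stouffer_liptak,
    total_covered_bases,
)


def _track(positions, pvals, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "p_raw": pvals},
        index=[f"cg{i:08d}" for i in range(len(positions))],
    )


def _zero_acf():
    return AcfEstimate(bins=[(1, 50), (51, 100), (101, 500)],
                       rho=np.zeros(3), n_pairs=np.zeros(3, int))


class TestStoufferLiptak:
    def test_independent_pair(self):
        # z = 2 * 1.6449 / sqrt(2) -> p ~ 0.01001
        got = stouffer_liptak([0.05, 0.05])
        expect = stats.norm.sf(2 * stats.norm.isf(0.05) / np.sqrt(2))
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.01001, rel=1e-2)

    def test_single_identity(self):
        assert stouffer_liptak([0.123]) == pytest.approx(0.123, rel=1e-12)

    def test_fully_dependent_pair(self):
        got = stouffer_liptak([0.05, 0.05], np.ones((2, 2)))
        assert got == pytest.approx(0.05, rel=1e-6)

    def test_non_psd_repaired(self):
        sigma = np.array([[1.0, 0.9, -0.9],
                          [0.9, 1.0, 0.9],
                          [-0.9, 0.9, 1.0]])  # not PSD
        p = stouffer_liptak([0.05, 0.05, 0.05], sigma)
        assert 0.0 < p < 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            stouffer_liptak([])

    def test_monotone_in_member_p(self):
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        p_hi = stouffer_liptak([0.05, 0.20], sigma)
        p_lo = stouffer_liptak([0.05, 0.10], sigma)
        assert p_lo <= p_hi


class TestAcf:
    def test_independent_null_near_zero(self):
        r = np.random.default_rng(0)
        tr = _track(np.arange(1, 10_001) * 60, r.uniform(size=10_000))
        acf = estimate_acf(tr)
        assert np.all(np.abs(acf.rho) < 0.05)

    def test_duplicated_track_rho_one(self):
        r = np.random.default_rng(1)
        p = r.uniform(size=2000)
        pos = np.arange(2000) * 2000 + 1
        tr = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.concatenate([pos, pos + 10]),
            "p_raw": np.concatenate([p, p]),
        }, index=[f"cg{i:08d}" for i in range(4000)])
        acf = estimate_acf(tr)
        assert acf.rho[0] > 0.95

    def test_known_lag_correlation(self):
        """AR-like pairs with rho = 0.5 at 50 bp lag."""
        r = np.random.default_rng(2)
        z1 = r.normal(size=5000)
        z2 = 0.5 * z1 + np.sqrt(1 - 0.25) * r.normal(size=5000)
        pos = np.arange(5000) * 2000 + 1
        tr = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.concatenate([pos, pos + 50]),
            "p_raw": stats.norm.sf(np.concatenate([z1, z2])),
        }, index=[f"cg{i:08d}" for i in range(10_000)])
        acf = estimate_acf(tr)
        assert acf.rho[0] == pytest.approx(0.5, abs=0.05)

    def test_needs_two_probes(self):
        with pytest.raises(ValueError):
            estimate_acf(_track([100], [0.5]))


class TestSlkSmooth:
    def test_isolated_probe_unchanged(self):
        tr = _track([100, 5000], [0.01, 0.3])
        adj = slk_smooth(tr, _zero_acf())
        assert adj.iloc[0] == pytest.approx(0.01, rel=1e-12)
        assert adj.iloc[1] == pytest.approx(0.3, rel=1e-12)

    def test_three_probe_closed_form(self):
        tr = _track([100, 200, 300], [0.01, 0.01, 0.01])
        adj = slk_smooth(tr, _zero_acf())
        expect = stats.norm.sf(3 * stats.norm.isf(0.01) / np.sqrt(3))
        assert adj.iloc[1] == pytest.approx(expect, rel=1e-10)
        assert adj.iloc[1] == pytest.approx(2.87e-5, rel=0.05)

    def test_translation_invariance(self):
        r = np.random.default_rng(3)
        pos = np.sort(r.choice(100_000, size=50, replace=False)) + 1
        p = r.uniform(size=50)
        tr1 = _track(pos, p)
        tr2 = _track(pos + 1_000_000, p)
        acf = _zero_acf()
        assert np.allclose(slk_smooth(tr1, acf).to_numpy(),
                           slk_smooth(tr2, acf).to_numpy())


class TestFindRegions:
    def test_pair_within_dist(self):
        tr = _track([100, 500], [0.01, 0.01])
        adj = pd.Series([0.01, 0.01], index=tr.index)
        regions = find_regions(tr, adj)
        assert len(regions) == 1
        assert len(regions[0]["probe_ids"]) == 2

    def test_pair_beyond_dist(self):
        tr = _track([100, 700], [0.01, 0.01])
        adj = pd.Series([0.01, 0.01], index=tr.index)
        assert find_regions(tr, adj) == []

    def test_interior_nonsignificant_member(self):
        tr = _track([100, 300, 450], [0.01, 0.9, 0.01])
        adj = pd.Series([0.01, 0.9, 0.01], index=tr.index)
        regions = find_regions(tr, adj)
        assert len(regions) == 1
        assert regions[0]["start_pos"] == 100
        assert regions[0]["end_pos"] == 450
        assert len(regions[0]["probe_ids"]) == 3
        assert len(regions[0]["seed_probe_ids"]) == 2

    def test_single_seed_dropped(self):
        tr = _track([100, 5000], [0.01, 0.01])
        adj = pd.Series([0.01, 0.01], index=tr.index)
        assert find_regions(tr, adj) == []

    def test_duplicate_positions_error(self):
        tr = _track([100, 100], [0.1, 0.2])
        with pytest.raises(ValueError):
            make_track(tr)


class TestScoreAndSidak:
    def test_pair_closed_form(self):
        tr = _track([100, 400], [0.05, 0.05])
        region = {"chrom": "chr1", "start_pos": 100, "end_pos": 400,
                  "probe_ids": list(tr.index), "seed_probe_ids": list(tr.index)}
        got = score_region(region, tr, _zero_acf())
        assert got == pytest.approx(stouffer_liptak([0.05, 0.05]), rel=1e-12)

    def test_all_half_is_half(self):
        tr = _track([100, 200, 300], [0.5, 0.5, 0.5])
        region = {"chrom": "chr1", "start_pos": 100, "end_pos": 300,
                  "probe_ids": list(tr.index), "seed_probe_ids": list(tr.index)}
        assert score_region(region, tr, _zero_acf()) == pytest.approx(0.5, abs=1e-10)

    def test_calibration_under_correlated_null(self):
        """Scored p uniform when regions are drawn from the matching MVN."""
        rho = 0.4
        sigma = np.full((4, 4), rho)
        np.fill_diagonal(sigma, 1.0)
        L = np.linalg.cholesky(sigma)
        r = np.random.default_rng(4)
        z = r.normal(size=(2000, 4)) @ L.T
        pvals = [stouffer_liptak(stats.norm.sf(row), sigma) for row in z]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sidak_closed_form(self):
        assert sidak_correct(0.01, 1000, 100_000) == pytest.approx(
            1 - 0.99 ** 100, rel=1e-10
        )
        assert sidak_correct(0.01, 1000, 100_000) == pytest.approx(0.6340, abs=2e-4)

    def test_sidak_ratio_one_identity(self):
        assert sidak_correct(0.037, 500, 500) == pytest.approx(0.037, rel=1e-12)

    def test_sidak_tiny_p_no_underflow(self):
        got = sidak_correct(1e-12, 10, 10 * 100_000)
        assert got == pytest.approx(1e-7, rel=1e-4)

    def test_sidak_validation(self):
        with pytest.raises(ValueError):
            sidak_correct(0.01, 0, 100)
        with pytest.raises(ValueError):
            sidak_correct(0.01, 200, 100)

    def test_monotone_region_score(self):
        tr1 = _track([100, 200, 300], [0.05, 0.2, 0.3])
        tr2 = _track([100, 200, 300], [0.05, 0.1, 0.3])
        region = {"chrom": "chr1", "start_pos": 100, "end_pos": 300,
                  "probe_ids": list(tr1.index), "seed_probe_ids": list(tr1.index)}
        acf = _zero_acf()
        assert score_region(region, tr2, acf) <= score_region(region, tr1, acf)


class TestCoverage:
    def test_covered_bases_rule(self):
        tr = _track([100, 200, 2000], [0.5, 0.5, 0.5])
        # gaps: 100 (kept), 1800 (capped at 500), final probe adds 500
        assert total_covered_bases(tr, dist=500) == 100 + 500 + 500

    def test_single_probe_chromosome(self):
        tr = _track([100], [0.5])
        assert total_covered_bases(tr, dist=500) == 500


class TestDmrRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            DmrRecord(chrom="chr1", start=100, end=100, n_probes=2, n_seeds=2,
                      probe_ids=["a", "b"], p_region=0.1, p_sidak=0.2)
        with pytest.raises(ValueError):
            DmrRecord(chrom="chr1", start=100, end=200, n_probes=1, n_seeds=1,
                      probe_ids=["a"], p_region=0.1, p_sidak=0.2)

    def test_sidak_geq_region_when_ratio_geq_1(self):
        p_region = 0.013
        assert sidak_correct(p_region, 100, 1000) >= p_region


class TestCallDmrs:
    def test_nonoverlapping_and_sorted(self, small_study):
        from methylrestore.combp import call_dmrs
        from methylrestore.ewas import run_ewas

        res = run_ewas(small_study["meth"],
                       small_study["truth"].true_cell_proportions,
                       contrasts=("PN",))
        _, records = call_dmrs(res, "PN")
        by_chrom = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1  # half-open non-overlap
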