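"""Genome scans: map function, Haley-Knott probabilities, single-locus
scan against an ordinary-regression oracle, epistasis, forward mapping."""

import numpy as np
import pandas as pd
import pytest

from pedqtl import (
    GenomeMap,
    GenotypeData,
    forward_multiple_qtl,
    genotype_probabilities,
    haldane,
    scan_one,
    scan_two,
)


def _ols_lrt_oracle(y, X, G, coding="additive+dominance"):
    """Brute-force per-marker likelihood ratio under iid errors, fully
    independent of the scan implementation (explicit lstsq per marker,
    missing rows dropped by hand)."""
    out = []
    for j in range(G.shape[1]):
        g = G[:, j]
        keep = ~np.isnan(g)
        yk, Xk, gk = y[keep], X[keep], g[keep]
        n = keep.sum()
        b0 = np.linalg.lstsq(Xk, yk, rcond=None)[0]
        rss0 = float(np.sum((yk - Xk @ b0) ** 2))
        cols = [gk - 1.0]
        if coding == "additive+dominance" and len(np.unique(gk)) > 2:
            cols.append((gk == 1.0).astype(float))
        M = np.column_stack([Xk] + cols)
        b1 = np.linalg.lstsq(M, yk, rcond=None)[0]
        rss1 = float(np.sum((yk - M @ b1) ** 2))
        out.append(n * np.log(rss0 / rss1) if len(np.unique(gk)) > 1 else np.nan)
    return np.array(out)


class TestHaldane:
    def test_values(self):
        assert haldane(0.0) == 0.0
        assert haldane(100.0) == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-15)
        assert haldane(1e7) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_below_half(self):
        d = np.linspace(0, 500, 200)
        r = haldane(d)
        assert np.all(np.diff(r) > 0) and np.all(r < 0.5)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            haldane(-1.0)


def _toy_map():
    return GenomeMap(pd.DataFrame({
        "marker": ["a1", "a2", "a3"], "chrom": ["1", "1", "1"],
        "pos_cm": [0.0, 20.0, 40.0]}))


class TestGenotypeProbabilities:
    def test_typed_marker_point_mass(self):
        gd = GenotypeData(["i"], ["a1", "a2", "a3"], np.array([[0.0, 2.0, 1.0]]))
        tab, P = genotype_probabilities(gd, _toy_map(),
                                        positions=pd.DataFrame({"chrom": ["1"], "pos_cm": [20.0]}))
        assert np.allclose(P[0, 0], (0, 0, 1))

    def test_midpoint_between_homozygotes_hand_formula(self):
        # both flanks genotype 0, 20 cM interval, query at the midpoint
        gd = GenotypeData(["i"], ["a1", "a2", "a3"],
                          np.array([[0.0, 0.0, np.nan]]))
        tab, P = genotype_probabilities(gd, _toy_map(),
                                        positions=pd.DataFrame({"chrom": ["1"], "pos_cm": [10.0]}))
        r = haldane(10.0)
        # per gamete: P(b_t = 0 | b_L = 0, b_R = 0) = (1-r)^2 / ((1-r)^2 + r^2)
        q0 = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        expect = np.array([q0**2, 2 * q0 * (1 - q0), (1 - q0) ** 2])
        assert np.max(np.abs(P[0, 0] - expect)) < 1e-10

    def test_no_information_gives_f2_prior(self):
        gd = GenotypeData(["i"], ["a1", "a2", "a3"],
                          np.array([[np.nan, np.nan, np.nan]]))
        tab, P = genotype_probabilities(gd, _toy_map(),
                                        positions=pd.DataFrame({"chrom": ["1"], "pos_cm": [15.0]}))
        assert np.allclose(P[0, 0], (0.25, 0.5, 0.25))

    def test_probabilities_sum_to_one(self, small_ail, rng):
        _, ped, gmap, geno, last = small_ail
        gd = geno.subset(last[:30])
        M = gd.matrix.copy()
        M[rng.random(M.shape) < 0.1] = np.nan
        gd = GenotypeData(gd.ids, gd.markers, M)
        _, P = genotype_probabilities(gd, gmap, step=7.0)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)

    def test_unknown_chromosome_raises(self):
        gd = GenotypeData(["i"], ["a1", "a2", "a3"], np.array([[0.0, 1.0, 2.0]]))
        with pytest.raises(ValueError, match="unknown chromosome"):
            genotype_probabilities(gd, _toy_map(),
                                   positions=pd.DataFrame({"chrom": ["7"], "pos_cm": [5.0]}))


@pytest.fixture(scope="module")
def iid_data():
    rng = np.random.default_rng(5)
    n, m = 50, 20
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    G[rng.random((n, m)) < 0.07] = np.nan
    G[:, 3] = 1.0  # monomorphic marker
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = rng.standard_normal(n) + 0.8 * np.nan_to_num(G[:, 7] - 1.0)
    return y, X, G


class TestScanOne:
    def test_matches_ols_oracle(self, iid_data):
        y, X, G = iid_data
        res = scan_one(y, X, genotypes=G, sigma=None)
        expect = _ols_lrt_oracle(y, X, G)
        got = res.table["lrt"].to_numpy()
        ok = res.table["testable"].to_numpy()
        assert np.nanmax(np.abs(got[ok] - expect[ok])) < 1e-8

    def test_sigma_scale_invariance(self, iid_data):
        # LRT is invariant to the scale of sigma: sigma = c*I equals OLS
        y, X, G = iid_data
        a = scan_one(y, X, genotypes=G, sigma=3.7 * np.eye(len(y)))
        b = scan_one(y, X, genotypes=G, sigma=None)
        assert np.allclose(a.table["lrt"], b.table["lrt"], atol=1e-8, equal_nan=True)

    def test_monomorphic_flagged_untestable(self, iid_data):
        y, X, G = iid_data
        res = scan_one(y, X, genotypes=G)
        row = res.table.iloc[3]
        assert not row["testable"] and np.isnan(row["lrt"]) and row["df"] == 0

    def test_relabeling_symmetry_under_iid(self, iid_data):
        y, X, G = iid_data
        perm = np.random.default_rng(11).permutation(len(y))
        a = scan_one(y, X, genotypes=G)
        b = scan_one(y[perm], X[perm], genotypes=G[perm])
        assert np.allclose(a.table["lrt"], b.table["lrt"], atol=1e-8, equal_nan=True)

    def test_whitening_equals_prewhitened_identity_scan(self, rng):
        n, m = 40, 8
        A = rng.standard_normal((n, n))
        sigma = A @ A.T / n + np.eye(n)
        L = np.linalg.cholesky(sigma)
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        P = rng.dirichlet(np.ones(3), size=(n, m))  # valid probability codings
        res_sig = scan_one(y, X, probabilities=P, sigma=sigma)
        # pre-whiten everything by hand and scan with identity covariance;
        # the probability container just carries the whitened codings
        Li = np.linalg.inv(L)
        aw = Li @ (P[:, :, 2] - P[:, :, 0])
        dw = Li @ P[:, :, 1]
        Pw = np.zeros_like(P)
        Pw[:, :, 2] = aw
        Pw[:, :, 1] = dw
        res_id = scan_one(Li @ y, Li @ X, probabilities=Pw, sigma=None)
        assert np.allclose(res_sig.table["lrt"], res_id.table["lrt"], atol=1e-10)

    def test_missing_at_marker_only_affects_that_marker(self, iid_data):
        y, X, G = iid_data
        G2 = G.copy()
        G2[:10, 5] = np.nan
        a = scan_one(y, X, genotypes=G).table
        b = scan_one(y, X, genotypes=G2).table
        changed = ~np.isclose(a["lrt"], b["lrt"], equal_nan=True)
        assert set(np.where(changed)[0]) <= {5}

    def test_lod_lrt_p_consistency(self, iid_data):
        from scipy import stats
        y, X, G = iid_data
        t = scan_one(y, X, genotypes=G).table
        t = t[t["testable"]]
        assert np.allclose(t["lod"], t["lrt"] / (2 * np.log(10)))
        assert np.allclose(t["p"], stats.chi2.sf(t["lrt"], t["df"]))

    def test_not_pd_sigma_raises(self, iid_data):
        y, X, G = iid_data
        bad = -np.eye(len(y))
        with pytest.raises(ValueError, match="positive definite"):
            scan_one(y, X, genotypes=G, sigma=bad)

    def test_requires_exactly_one_input(self, iid_data):
        y, X, G = iid_data
        with pytest.raises(ValueError, match="exactly one"):
            scan_one(y, X)


@pytest.fixture(scope="module")
def pair_data():
    rng = np.random.default_rng(21)
    n, m = 80, 8
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.standard_normal(n) + 0.9 * (G[:, 1] - 1) * (G[:, 6] - 1)
    return y, np.ones((n, 1)), G


class TestScanTwo:
    def test_symmetric_in_pair_order(self, pair_data):
        y, X, G = pair_data
        a = scan_two(y, X, G, pairs=[(1, 6)])
        b = scan_two(y, X, G, pairs=[(6, 1)])
        assert a["lrt"][0] == pytest.approx(b["lrt"][0], abs=1e-10)

    def test_planted_interaction_is_top_pair(self, pair_data):
        y, X, G = pair_data
        tab = scan_two(y, X, G)
        best = tab.loc[tab["lrt"].idxmax()]
        assert {best["marker1"], best["marker2"]} == {"m1", "m6"}

    def test_identical_pair_raises(self, pair_data):
        y, X, G = pair_data
        with pytest.raises(ValueError, match="same locus"):
            scan_two(y, X, G, pairs=[(2, 2)])

    def test_min_separation_filter(self, pair_data):
        y, X, G = pair_data
        gmap = GenomeMap(pd.DataFrame({
            "marker": [f"m{j}" for j in range(8)],
            "chrom": ["1"] * 8,
            "pos_cm": np.arange(8) * 5.0}))
        tab = scan_two(y, X, G, gmap=gmap, min_sep_cM=20.0)
        pos = {f"m{j}": j * 5.0 for j in range(8)}
        assert all(abs(pos[r.marker2] - pos[r.marker1]) >= 20.0 for r in tab.itertuples())

    def test_collinear_interaction_flagged(self):
        n = 30
        rng = np.random.default_rng(2)
        G = np.zeros((n, 2))
        G[:, 0] = rng.integers(0, 3, n)
        G[:, 1] = G[:, 0]  # duplicated locus: interaction adds nothing
        y = rng.standard_normal(n)
        tab = scan_two(y, np.ones((n, 1)), G, pairs=[(0, 1)])
        assert not tab["testable"][0] or tab["df"][0] == 0


class TestForwardMultipleQTL:
    def test_no_locus_above_threshold(self, rng):
        G = rng.integers(0, 3, size=(60, 10)).astype(float)
        y = rng.standard_normal(60)
        out = forward_multiple_qtl(y, np.ones((60, 1)), G, threshold=1e6)
        assert out["selected"] == [] and out["effects"] == {}

    def test_two_unlinked_qtl_recovered(self):
        rng = np.random.default_rng(8)
        n, m = 300, 30
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        y = (G[:, 4] - 1) * 1.0 + (G[:, 22] - 1) * 1.0 + rng.standard_normal(n)
        out = forward_multiple_qtl(y, np.ones((n, 1)), G, threshold=15.0, max_qtl=4)
        assert {"m4", "m22"} <= set(out["selected"][:2])
        assert out["effects"]["m4:a"] == pytest.approx(1.0, abs=0.3)

    def test_invalid_max_qtl(self, rng):
        with pytest.raises(ValueError, match="max_qtl"):
            forward_multiple_qtl(np.zeros(5), np.ones((5, 1)),
                                 np.zeros((5, 2)), threshold=1.0, max_qtl=0)
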