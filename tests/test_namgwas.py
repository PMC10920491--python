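"""Q+K scan machinery: marker preparation, kinship expectations under
the pedigree, OLS equivalence, calibration and threshold arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatnam import namgwas
from wheatnam.core import GenotypeMatrix

from conftest import random_genotype_matrix


def identity_K(ids):
    return pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)


class TestPrepareScanMarkers:
    def test_duplicate_column_single_survivor(self):
        rng = np.random.default_rng(0)
        col = rng.choice([0.0, 2.0], 100)
        d = pd.DataFrame({"m1": col, "m2": col.copy(),
                          "m3": rng.choice([0.0, 2.0], 100)})
        d.index = [f"g{i}" for i in range(100)]
        kept = namgwas.prepare_scan_markers(GenotypeMatrix(d), min_minor_hom=5)
        assert "m1" in kept and "m2" not in kept

    def test_minor_hom_below_15_dropped(self):
        d = pd.DataFrame(
            {
                "rare": [2.0] * 14 + [0.0] * 86,
                "common": [2.0] * 40 + [0.0] * 60,
            },
            index=[f"g{i}" for i in range(100)],
        )
        kept = namgwas.prepare_scan_markers(GenotypeMatrix(d))
        assert kept == ["common"]

    def test_subset_dependence(self, nam_small):
        G, ped, *_ = nam_small
        full = G.subset(genotypes=ped.index)
        half = G.subset(genotypes=ped.index[: len(ped) // 2])
        assert set(namgwas.prepare_scan_markers(full)) != set(
            namgwas.prepare_scan_markers(half)
        )


class TestKinship:
    def test_duplicated_genotypes_equal_offdiagonals(self):
        G = random_genotype_matrix(5, 60, seed=1)
        G.dosages.iloc[1] = G.dosages.iloc[0]
        K = namgwas.compute_kinship(G, skim_r=1.01 - 1e-9, markers=None) \
            if False else namgwas.compute_kinship(G, skim_r=1.0)
        a, b, c = G.genotype_ids[0], G.genotype_ids[1], G.genotype_ids[2]
        assert K.loc[a, c] == pytest.approx(K.loc[b, c], abs=1e-9)

    def test_unrelated_founders_near_zero_offdiagonal(self):
        G = random_genotype_matrix(40, 800, seed=2)
        K = namgwas.compute_kinship(G, skim_r=1.0)
        off = K.to_numpy()[np.triu_indices(40, 1)]
        diag = np.diag(K.to_numpy())
        assert np.abs(off).mean() < 0.1 * diag.mean()

    def test_full_sibs_twice_half_sibs(self):
        # pedigree expectation: full sibs share ~1/2, half sibs ~1/4 of
        # segregating founder alleles, so kinship ratio ~2
        rng = np.random.default_rng(3)
        m = 2000
        founders = [rng.integers(0, 2, (2, m)) for _ in range(4)]

        def gamete(par):
            pick = rng.integers(0, 2, m)
            return par[pick, np.arange(m)]

        def child(pa, pb):
            return (gamete(pa) + gamete(pb)).astype(float)

        full1, full2 = child(founders[0], founders[1]), child(founders[0], founders[1])
        half = child(founders[0], founders[2])
        # a large unrelated panel anchors the allele-frequency centering
        unrelated = [
            child(rng.integers(0, 2, (2, m)), rng.integers(0, 2, (2, m)))
            for _ in range(60)
        ]
        d = pd.DataFrame(
            [full1, full2, half] + unrelated,
            index=["f1", "f2", "h1"] + [f"x{i}" for i in range(60)],
        )
        d.columns = [f"mk{j}" for j in range(m)]
        K = namgwas.compute_kinship(GenotypeMatrix(d), skim_r=1.0)
        assert K.loc["f1", "f2"] / K.loc["f1", "h1"] == pytest.approx(2.0, rel=0.35)


class TestScan:
    def test_identity_kinship_matches_ols(self):
        G = random_genotype_matrix(100, 30, seed=4)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=100), index=G.genotype_ids)
        Q = pd.Series("P1", index=G.genotype_ids)
        sc = namgwas.scan(y, G, Q, identity_K(G.genotype_ids))
        import statsmodels.api as sm

        for mk in G.marker_ids[:10]:
            X = sm.add_constant(G.dosages[mk].to_numpy())
            p_ols = sm.OLS(y.to_numpy(), X).fit().pvalues[1]
            assert abs(sc.loc[mk, "score"] + np.log10(p_ols)) < 0.01

    def test_effect_sign_flips_with_reference_swap(self):
        G = random_genotype_matrix(80, 20, seed=6)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=80), index=G.genotype_ids)
        Q = pd.Series("P1", index=G.genotype_ids)
        K = identity_K(G.genotype_ids)
        sc1 = namgwas.scan(y, G, Q, K)
        flipped = GenotypeMatrix(2.0 - G.dosages)
        sc2 = namgwas.scan(y, flipped, Q, K)
        assert np.allclose(sc1["effect"], -sc2["effect"], atol=1e-9)
        assert np.allclose(sc1["p"], sc2["p"], atol=1e-12)

    def test_row_order_invariance(self):
        G = random_genotype_matrix(60, 15, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=60), index=G.genotype_ids)
        Q = pd.Series("P1", index=G.genotype_ids)
        K = identity_K(G.genotype_ids)
        sc1 = namgwas.scan(y, G, Q, K)
        perm = list(rng.permutation(G.genotype_ids))
        G2 = G.subset(genotypes=perm)
        sc2 = namgwas.scan(y.loc[perm], G2, Q.loc[perm], K.loc[perm, perm])
        assert np.allclose(sc1["score"], sc2["score"], atol=1e-8)

    def test_marker_confounded_with_population_reported_na(self, nam_small):
        G, ped, *_ = nam_small
        prog = G.subset(genotypes=ped.index)
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(size=prog.n_genotypes), index=prog.genotype_ids)
        Q = prog.populations
        # fabricate a marker that is constant within every population
        prog.dosages["confounded"] = Q.map(
            {p: float(2 * (i % 2)) for i, p in enumerate(Q.unique())}
        )
        K = identity_K(prog.genotype_ids)
        sc = namgwas.scan(y, prog, Q, K, markers=["confounded"])
        assert np.isnan(sc.loc["confounded", "score"])

    def test_covariate_scan_masks_covariate_and_prunes_duplicates(self):
        G = random_genotype_matrix(80, 10, seed=11)
        rng = np.random.default_rng(12)
        y = pd.Series(
            G.dosages["mk000"] * 0.8 + rng.normal(size=80), index=G.genotype_ids
        )
        Q = pd.Series("P1", index=G.genotype_ids)
        K = identity_K(G.genotype_ids)
        with pytest.warns(UserWarning, match="collinear"):
            sc = namgwas.covariate_scan(y, G, Q, K, ["mk000", "mk000"])
        assert np.isnan(sc.loc["mk000", "score"])
        base = namgwas.scan(y, G, Q, K)
        assert base.loc["mk000", "score"] > sc["score"].max()


class TestThresholds:
    def test_independent_markers_bonferroni_limit(self):
        rng = np.random.default_rng(13)
        n, m = 2000, 8  # n >> m keeps sampling noise in r tiny
        d = pd.DataFrame(
            rng.choice([0.0, 2.0], (n, m)),
            columns=[f"mk{j}" for j in range(m)],
        )
        from wheatnam.markermap import empty_map

        mmap = empty_map(d.columns)
        for j, mk in enumerate(d.columns):
            mmap.loc[mk] = ["1A", 1000 * (j + 1), "curated"]
        thr, meff = namgwas.significance_threshold(d, mmap)
        assert meff == pytest.approx(m, abs=0.5)
        assert thr == pytest.approx(-np.log10(0.05 / m), abs=0.05)

    def test_identical_markers_collapse_to_one_test(self):
        rng = np.random.default_rng(14)
        col = rng.choice([0.0, 2.0], 500)
        d = pd.DataFrame({f"mk{j}": col for j in range(6)})
        from wheatnam.markermap import empty_map

        mmap = empty_map(d.columns)
        for j, mk in enumerate(d.columns):
            mmap.loc[mk] = ["1A", 1000 * (j + 1), "curated"]
        thr, meff = namgwas.significance_threshold(d, mmap)
        assert meff == pytest.approx(1.0, abs=1e-6)
        assert thr == pytest.approx(-np.log10(0.05), abs=1e-6)

    def test_printed_threshold_inversion(self):
        # an effective marker count of 4669 corresponds to a 4.97
        # threshold at corrected P = 0.05
        assert namgwas.threshold_from_meff(4669) == pytest.approx(4.97, abs=0.005)


class TestInflation:
    def test_all_half_pvalues_give_lambda_one(self):
        assert namgwas.inflation_factor([0.5] * 100) == pytest.approx(1.0)

    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(15)
        lam = namgwas.inflation_factor(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.03)

    def test_doubled_chi2_doubles_lambda(self):
        rng = np.random.default_rng(16)
        chi2 = stats.chi2.rvs(1, size=20_000, random_state=17)
        p = stats.chi2.sf(2.0 * chi2, 1)
        assert namgwas.inflation_factor(p) == pytest.approx(2.0, abs=0.1)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            namgwas.inflation_factor([0.0] * 20)
        with pytest.raises(ValueError):
            namgwas.inflation_factor([0.5] * 5)
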