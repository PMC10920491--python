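"""QTL calling: closed-form LD-decay crossings, greedy suppression
logic, interval growth, cross-trial merging and variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from wheatnam import qtlcall
from wheatnam.core import GenotypeMatrix
from wheatnam.markermap import empty_map
from wheatnam.namgwas import compute_kinship

MB = qtlcall.MB


def scan_frame(rows):
    """rows: (marker, chrom, bp_mb, score, effect)"""
    df = pd.DataFrame(
        rows, columns=["marker", "chrom", "bp", "score", "effect"]
    ).set_index("marker")
    df["bp"] = (df["bp"] * MB).astype(int)
    df["p"] = 10.0 ** (-df["score"])
    return df


def ar1_dosages(n, m, spacing_mb, decay_mb, seed):
    """Markers on one chromosome whose pairwise R2 decays as
    exp(-distance / decay_mb), via a stationary AR(1) latent process."""
    rng = np.random.default_rng(seed)
    rho = np.exp(-spacing_mb / (2 * decay_mb))  # r = sqrt(R2)
    X = np.empty((n, m))
    X[:, 0] = rng.normal(size=n)
    for j in range(1, m):
        X[:, j] = rho * X[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(size=n)
    d = pd.DataFrame(X, index=[f"g{i}" for i in range(n)],
                     columns=[f"mk{j:03d}" for j in range(m)])
    mmap = empty_map(d.columns)
    for j, mk in enumerate(d.columns):
        mmap.loc[mk] = ["1A", int(j * spacing_mb * MB) + 1, "curated"]
    return d, mmap


class TestLdDecayWindow:
    def test_exponential_decay_closed_form(self):
        # R2(d) = exp(-d/10 Mb) crosses 0.2 at 10 ln 5 = 16.09 -> 17 Mb
        d, mmap = ar1_dosages(n=800, m=120, spacing_mb=1.0, decay_mb=10.0, seed=1)
        prof = qtlcall.ld_decay_window(d, mmap, critical_r2=0.2)
        assert prof.window_mb == pytest.approx(17, abs=1)

    def test_pooling_consistency_across_chromosomes(self):
        d1, m1 = ar1_dosages(500, 80, 1.0, 10.0, seed=2)
        d2, m2 = ar1_dosages(500, 80, 1.0, 10.0, seed=3)
        d2.columns = [f"x{j:03d}" for j in range(80)]
        m2.index = d2.columns
        m2["chrom"] = "2B"
        pooled = pd.concat([d1, d2], axis=1)
        mmap = pd.concat([m1, m2])
        w_single = qtlcall.ld_decay_window(d1, m1).window_mb
        w_pooled = qtlcall.ld_decay_window(pooled, mmap).window_mb
        assert abs(w_single - w_pooled) <= 1

    def test_no_decay_raises_with_guidance(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=300)
        d = pd.DataFrame({f"mk{j}": col + rng.normal(0, 0.01, 300) for j in range(20)})
        mmap = empty_map(d.columns)
        for j, mk in enumerate(d.columns):
            mmap.loc[mk] = ["1A", int(j * 30 * MB) + 1, "curated"]
        with pytest.raises(ValueError, match="critical"):
            qtlcall.ld_decay_window(d, mmap, critical_r2=0.2)


class TestCallPeaks:
    def test_two_distant_peaks_both_called(self):
        sc = scan_frame([("a", "1A", 10, 6.0, 1.0), ("b", "1A", 40, 5.5, 1.0)])
        peaks = qtlcall.call_peaks(sc, threshold=5.0, window_mb=18)
        assert set(peaks.index) == {"a", "b"}

    def test_nearby_peaks_suppressed_to_highest(self):
        sc = scan_frame([("a", "1A", 10, 6.0, 1.0), ("b", "1A", 20, 5.5, 1.0)])
        peaks = qtlcall.call_peaks(sc, threshold=5.0, window_mb=18)
        assert list(peaks.index) == ["a"]

    def test_no_significant_markers_empty(self):
        sc = scan_frame([("a", "1A", 10, 3.0, 1.0)])
        assert qtlcall.call_peaks(sc, threshold=5.0, window_mb=18).empty

    def test_invariant_to_marker_shuffling(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"m{i}", "2D", float(rng.uniform(0, 500)), float(rng.uniform(4, 9)), 1.0)
            for i in range(40)
        ]
        sc = scan_frame(rows)
        shuffled = sc.sample(frac=1.0, random_state=6)
        p1 = qtlcall.call_peaks(sc, 5.0, 18)
        p2 = qtlcall.call_peaks(shuffled, 5.0, 18)
        assert list(p1.index) == list(p2.index)

    def test_same_chromosome_only_suppression(self):
        sc = scan_frame([("a", "1A", 10, 6.0, 1.0), ("b", "1B", 12, 5.5, 1.0)])
        peaks = qtlcall.call_peaks(sc, threshold=5.0, window_mb=18)
        assert set(peaks.index) == {"a", "b"}


class TestQtlInterval:
    def test_isolated_peak_zero_width(self):
        sc = scan_frame([("a", "1A", 10, 6.0, 1.0), ("b", "1A", 12, 2.0, 1.0)])
        assert qtlcall.qtl_interval(sc, "a", 5.0, 18) == (10 * MB, 10 * MB)

    def test_run_of_significant_markers_spanned(self):
        rows = [(f"m{i}", "1A", 10 + i, 6.0 - 0.1 * i, 1.0) for i in range(5)]
        rows.append(("far", "1A", 100, 7.0, 1.0))
        sc = scan_frame(rows)
        lo, hi = qtlcall.qtl_interval(sc, "m0", 5.0, 18)
        assert (lo, hi) == (10 * MB, 14 * MB)

    def test_interval_confined_to_window(self):
        rows = [(f"m{i}", "1A", 10 + 10 * i, 6.0, 1.0) for i in range(5)]
        sc = scan_frame(rows)
        lo, hi = qtlcall.qtl_interval(sc, "m0", 5.0, window_mb=18)
        assert hi <= (10 + 18) * MB

    def test_insignificant_peak_rejected(self):
        sc = scan_frame([("a", "1A", 10, 3.0, 1.0)])
        with pytest.raises(ValueError):
            qtlcall.qtl_interval(sc, "a", 5.0, 18)


class TestMergeQtls:
    def test_same_marker_three_trials_single_qtl(self):
        peak = ("AX.94546744", "4D", 1.4, 13.8, -0.78)
        tables = {
            t: scan_frame([peak]).assign(trait="Yr")
            for t in ("Core17", "Core18", "Full21")
        }
        recs = qtlcall.merge_qtls(tables, window_mb=18)
        assert len(recs) == 1
        assert recs[0].trials == ["Core17", "Core18", "Full21"]
        assert recs[0].name.startswith("QYr.")

    def test_distant_opposite_sign_peaks_stay_separate(self):
        t1 = scan_frame([("a", "5A", 100, 6.0, 2.0)]).assign(trait="Ph")
        t2 = scan_frame([("b", "5A", 160, 6.0, -2.0)]).assign(trait="Ph")
        recs = qtlcall.merge_qtls({"t1": t1, "t2": t2}, window_mb=18)
        assert len(recs) == 2

    def test_single_trial_peak_recorded(self):
        t1 = scan_frame([("a", "2B", 26.6, 6.3, -0.96)]).assign(trait="Ft")
        recs = qtlcall.merge_qtls({"Core19": t1}, window_mb=18)
        assert len(recs) == 1
        assert recs[0].trials == ["Core19"]

    def test_cross_trial_shift_within_3x_window_merges(self):
        # peaks 40 Mb apart with the same sign merge under the 54 Mb
        # (3 x 18) default, mirroring cross-trial peak drift
        t1 = scan_frame([("a", "4A", 700, 10.0, -0.7)]).assign(trait="Ft")
        t2 = scan_frame([("b", "4A", 740, 10.3, -0.8)]).assign(trait="Ft")
        recs = qtlcall.merge_qtls({"t1": t1, "t2": t2}, window_mb=18)
        assert len(recs) == 1

    def test_conflicting_signs_at_same_bp_flagged(self):
        t1 = scan_frame([("a", "1A", 50, 6.0, 1.0)]).assign(trait="Ft")
        t2 = scan_frame([("b", "1A", 50, 6.0, -1.0)]).assign(trait="Ft")
        recs = qtlcall.merge_qtls({"t1": t1, "t2": t2}, window_mb=18)
        assert len(recs) == 2
        assert all(r.flagged for r in recs)

    def test_names_ordered_by_chromosome_then_bp(self):
        t1 = scan_frame(
            [
                ("a", "2B", 100, 6.0, 1.0),
                ("b", "2B", 300, 6.0, 1.0),
                ("c", "1A", 50, 6.0, 1.0),
            ]
        ).assign(trait="Ft")
        recs = qtlcall.merge_qtls({"t1": t1}, window_mb=18, lab="nam")
        names = [r.name for r in recs]
        assert names == ["QFt.nam-1A.1", "QFt.nam-2B.1", "QFt.nam-2B.2"]


class TestMultiQtlVariance:
    def make_panel(self, seed=7, n=600, m=40):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame(
            rng.choice([0.0, 2.0], (n, m)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"mk{j}" for j in range(m)],
        )
        G = GenotypeMatrix(d)
        Q = pd.Series("P1", index=d.index)
        K = compute_kinship(G, skim_r=1.0)
        return G, Q, K, rng

    def test_recovers_planted_share(self):
        G, Q, K, rng = self.make_panel()
        g = G.dosages["mk0"]
        beta = np.sqrt(0.10 / g.var())  # 10% of unit total variance
        y = pd.Series(
            beta * g + rng.normal(0, np.sqrt(0.90), len(g)), index=g.index
        )
        shares = qtlcall.multi_qtl_variance(y, G, Q, K, ["mk0", "mk1"])
        assert shares["mk0"] == pytest.approx(10.0, abs=3.0)
        assert shares["mk1"] < 1.0

    def test_duplicate_peak_flagged_collinear(self):
        G, Q, K, rng = self.make_panel(seed=8)
        y = pd.Series(rng.normal(size=G.n_genotypes), index=G.genotype_ids)
        with pytest.warns(UserWarning, match="collinear"):
            shares = qtlcall.multi_qtl_variance(y, G, Q, K, ["mk0", "mk0"])
        assert np.isnan(shares.iloc[1])

    def test_null_marker_small_share(self):
        hits = 0
        for r in range(10):
            G, Q, K, rng = self.make_panel(seed=20 + r, n=400, m=10)
            y = pd.Series(rng.normal(size=400), index=G.genotype_ids)
            shares = qtlcall.multi_qtl_variance(y, G, Q, K, ["mk0"])
            hits += shares["mk0"] < 1.0
        assert hits >= 9

    def test_shares_bounded_by_model_r2(self):
        G, Q, K, rng = self.make_panel(seed=9)
        g = G.dosages["mk0"]
        y = pd.Series(0.5 * g + rng.normal(size=len(g)), index=g.index)
        peaks = ["mk0", "mk1", "mk2"]
        shares = qtlcall.multi_qtl_variance(y, G, Q, K, peaks)
        # total model R2 (OLS on all peaks) bounds the sum of shares
        X = np.column_stack([np.ones(len(y))] + [G.dosages[m] for m in peaks])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - X @ beta
        r2 = 1 - resid.var() / y.to_numpy().var()
        assert shares.sum() <= 100 * r2 + 1e-6
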