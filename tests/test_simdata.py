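"""The simulator must honour the breeding scheme's closed-form
expectations: Haldane recombination, backcross genome fractions and the
halving of residual heterozygosity under single-seed descent."""

import numpy as np
import pandas as pd
import pytest

from wheatnam import simdata as sd
from wheatnam.simdata import donor_genome_fraction


class TestGeneticMap:
    def test_uniform_spacing_three_markers(self):
        gm = sd.make_genetic_map(1, 3, 300_000_000, 150.0)
        assert list(gm.markers["bp"]) == [1, 150_000_001, 300_000_000]
        assert list(gm.markers["cM"]) == [0.0, 75.0, 150.0]

    def test_full_scale_map_invariants(self):
        gm = sd.make_genetic_map(21, 500)
        assert gm.n_markers == 10_500
        assert gm.chromosomes.index.is_unique
        for _, sub in gm.markers.groupby("chrom"):
            assert sub["bp"].is_monotonic_increasing
            assert sub["cM"].is_monotonic_increasing

    def test_deterministic_under_seed(self):
        a = sd.make_genetic_map(3, 20, seed=5, spacing="random")
        b = sd.make_genetic_map(3, 20, seed=5, spacing="random")
        pd.testing.assert_frame_equal(a.markers, b.markers)

    @pytest.mark.parametrize("bad", [dict(markers_per_chromosome=1),
                                     dict(chrom_length_bp=0),
                                     dict(chrom_length_cM=-1.0)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.make_genetic_map(2, **{"markers_per_chromosome": 10, **bad})


class TestMeiosis:
    def test_zero_distance_never_recombines(self):
        chroms = pd.DataFrame(
            {"length_bp": [1000], "length_cM": [100.0]},
            index=pd.Index(["1A"], name="chrom"),
        )
        markers = pd.DataFrame(
            {"chrom": ["1A", "1A"], "bp": [500, 501], "cM": [50.0, 50.0 + 1e-9]},
            index=pd.Index(["m1", "m2"], name="marker"),
        )
        gm = sd.GeneticMap(chroms, markers)
        parent = np.array([[0, 0], [1, 1]])
        rng = np.random.default_rng(0)
        rec = sum(
            (g := sd.simulate_meiosis(parent, gm, rng))[0] != g[1]
            for _ in range(2000)
        )
        assert rec == 0

    def test_haldane_fraction_at_50_cM(self, two_locus_map):
        # closed form: (1 - exp(-2*50/100)) / 2 = 0.3161
        parent = np.array([[0, 0], [1, 1]])
        rng = np.random.default_rng(1)
        n = 10_000
        rec = sum(
            (g := sd.simulate_meiosis(parent, two_locus_map, rng))[0] != g[1]
            for _ in range(n)
        )
        assert rec / n == pytest.approx(0.5 * (1 - np.exp(-1.0)), abs=0.015)

    def test_homozygous_parent_gamete_identical(self, small_map):
        hap = np.random.default_rng(2).integers(0, 2, small_map.n_markers)
        parent = np.vstack([hap, hap])
        gamete = sd.simulate_meiosis(parent, small_map, np.random.default_rng(3))
        assert np.array_equal(gamete, hap)


class TestBuildNam:
    def test_default_plan_initial_size_96(self):
        assert sd.CrossPlan().initial_population_size == 96

    def test_attrition_to_target_and_pedigree(self, nam_small):
        G, ped, founders, _ = nam_small
        assert (ped.groupby("population").size() == 60).all()
        assert G.n_genotypes == 4 * 60 + 5  # progeny + recurrent + 4 donors

    def test_recurrent_fraction_near_75pct(self, nam_small):
        G, ped, *_ = nam_small
        donor = donor_genome_fraction(G, ped)
        assert len(donor) >= 200
        assert 1 - donor.mean() == pytest.approx(0.75, abs=0.02)

    def test_heterozygosity_halves_per_selfing_generation(self, small_map):
        # Mendelian closed form: P(het at BC1F(g+1)) = 0.5 * (1/2)^g
        founders = sd.make_founders(small_map, n_donors=2, seed=21)
        for gens, expect in [(1, 0.25), (2, 0.125), (3, 0.0625), (4, 0.03125)]:
            plan = sd.CrossPlan(
                n_populations=2, selfing_generations=gens, target_size=None
            )
            G, ped = sd.build_nam(plan, founders, small_map, seed=30 + gens)
            fracs = []
            for gid, row in ped.iterrows():
                poly = G.dosages.loc[G.donor_ids[row["population"]]] > 0
                fracs.append((G.dosages.loc[gid, poly.to_numpy()] == 1).mean())
            n_cells = len(fracs) * int(poly.sum())
            se = np.sqrt(expect * (1 - expect) / n_cells)
            # loci within a genotype are correlated; allow a wide band
            assert np.mean(fracs) == pytest.approx(expect, abs=max(10 * se, 0.02))

    def test_alleles_subset_of_parents(self, nam_small):
        G, ped, *_ = nam_small
        for pop, members in G.populations.groupby(G.populations):
            donor = G.dosages.loc[G.donor_ids[pop]]
            prog = G.dosages.loc[members.index]
            # where the donor is reference-homozygous the cross cannot segregate
            fixed = donor == 0
            assert (prog.loc[:, fixed.to_numpy()] == 0).all().all()

    def test_bit_reproducible(self, small_map):
        founders = sd.make_founders(small_map, n_donors=2, seed=7)
        plan = sd.CrossPlan(n_populations=2, target_size=30)
        G1, p1 = sd.build_nam(plan, founders, small_map, seed=8)
        G2, p2 = sd.build_nam(plan, founders, small_map, seed=8)
        pd.testing.assert_frame_equal(G1.dosages, G2.dosages)
        pd.testing.assert_frame_equal(p1, p2)


class TestTrialLayout:
    def test_full21_scale_check_fraction_rounds_to_24pct(self):
        # 2100 plots, three checks with 295/285/444 replicates
        n_checks = 295 + 285 + 444
        entries = [f"e{i}" for i in range(4200 - n_checks)]
        layout = sd.build_trial_layout(
            entries,
            {"Robigus": 295, "Santiago": 285, "Theodore": 444},
            seed=1,
        )
        assert layout["plot"].nunique() == 2100
        assert (layout.groupby("plot").size() == 2).all()
        assert round(100 * layout.attrs["check_fraction"]) == 24
        # a replicated genotype never occupies both halves of one plot
        per_plot = layout.groupby("plot")["genotype"].nunique()
        assert (per_plot == 2).all()
        sizes = layout.drop_duplicates("plot").groupby("block").size()
        assert sizes.between(144, 156).all()

    def test_single_plot_two_distinct_entries(self):
        layout = sd.build_trial_layout(["a"], {"chk": 1}, seed=0,
                                       block_size_range=(1, 10))
        assert set(layout["genotype"]) == {"a", "chk"}

    def test_zero_checks(self):
        layout = sd.build_trial_layout(["a", "b", "c", "d"], {}, seed=0,
                                       block_size_range=(1, 10))
        assert not layout["is_check"].any()
        assert layout.attrs["check_fraction"] == 0.0

    def test_odd_entry_count_rejected(self):
        with pytest.raises(ValueError):
            sd.build_trial_layout(["a", "b", "c"], {}, seed=0,
                                  block_size_range=(1, 10))


class TestPhenotypes:
    def test_no_variance_no_qtl_gives_constant(self, nam_small):
        G, *_ = nam_small
        layout = sd.build_trial_layout(
            list(G.populations.index[:40]), {}, seed=3, block_size_range=(1, 30)
        )
        model = sd.TraitModel(trait="Ft", mean=100.0, residual_var=0.0)
        phe = sd.simulate_phenotypes(G, [model], layout, seed=4)
        assert (phe["value"] == 100.0).all()

    def test_planted_qtl_shifts_carriers(self, nam_small):
        G, *_ = nam_small
        # pick a marker segregating broadly across populations
        freq = G.dosages.loc[G.populations.index].mean() / 2
        marker = (freq - 0.25).abs().idxmin()
        layout = sd.build_trial_layout(
            list(G.populations.index), {}, seed=5, block_size_range=(1, 200)
        )
        model = sd.TraitModel(
            trait="Ft",
            mean=100.0,
            qtls=[sd.QtlEffect(marker, -1.0)],
            residual_var=0.25,
        )
        phe = sd.simulate_phenotypes(G, [model], layout, seed=6)
        means = phe.groupby("genotype")["value"].mean()
        dose = G.dosages[marker]
        hi = means[dose.reindex(means.index) == 2].mean()
        lo = means[dose.reindex(means.index) == 0].mean()
        n2 = (dose.reindex(means.index) == 2).sum()
        n0 = (dose.reindex(means.index) == 0).sum()
        se = np.sqrt(0.25 / n2 + 0.25 / n0)
        assert hi - lo == pytest.approx(-2.0, abs=4 * se + 0.05)

    def test_reproducible_under_seed(self, nam_small):
        G, *_ = nam_small
        layout = sd.build_trial_layout(
            list(G.populations.index[:20]), {}, seed=7, block_size_range=(1, 20)
        )
        model = sd.TraitModel(trait="Yr", mean=5.0)
        a = sd.simulate_phenotypes(G, [model], layout, seed=8)
        b = sd.simulate_phenotypes(G, [model], layout, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_layout_genotype_rejected(self, nam_small):
        G, *_ = nam_small
        layout = sd.build_trial_layout(["nope", "alsono"], {}, seed=9,
                                       block_size_range=(1, 10))
        with pytest.raises(KeyError):
            sd.simulate_phenotypes(G, [sd.TraitModel(trait="Ft")], layout, seed=1)


class TestInjection:
    def test_zero_rates_identity(self, nam_small):
        G, *_ = nam_small
        out = sd.inject_missing_and_errors(G, 0.0, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.dosages, G.dosages)

    def test_missing_rate_binomial(self):
        import wheatnam.core as core

        rng = np.random.default_rng(0)
        d = pd.DataFrame(rng.integers(0, 3, (1000, 1000)).astype(float))
        d.columns = d.columns.astype(str)
        d.index = d.index.astype(str)
        G = core.GenotypeMatrix(d)
        out = sd.inject_missing_and_errors(G, missing_rate=0.06, seed=2)
        frac = out.dosages.isna().to_numpy().mean()
        assert frac == pytest.approx(0.06, abs=0.001)

    def test_errors_shift_dosage_by_one(self, nam_small):
        G, *_ = nam_small
        out = sd.inject_missing_and_errors(G, 0.0, 0.2, seed=3)
        diff = (out.dosages - G.dosages).abs()
        assert diff.max().max() <= 1.0

    def test_mask_reproducible(self, nam_small):
        G, *_ = nam_small
        a = sd.inject_missing_and_errors(G, 0.05, 0.01, seed=4)
        b = sd.inject_missing_and_errors(G, 0.05, 0.01, seed=4)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
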