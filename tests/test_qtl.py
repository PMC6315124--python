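"""Interval mapping: map functions, imputation, cofactors, scans, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bilfreqsel as bf
from bilfreqsel.datatypes import InvalidParameterError, Qtl
from bilfreqsel.mapping import UndefinedEstimateError, empirical_quantile
from oracles import mc_conditional_dosage, type7_quantile


class TestKosambi:
    def test_reference_values(self):
        assert bf.kosambi_cm(0.0) == 0.0
        assert bf.kosambi_cm(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)
        assert bf.kosambi_inverse(0.0) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 0.499))
    def test_round_trip_inverse(self, r):
        assert bf.kosambi_inverse(bf.kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(0, 0.4999, 200)
        assert np.all(np.diff(bf.kosambi_cm(r)) > 0)

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            bf.kosambi_cm(0.5)
        with pytest.raises(InvalidParameterError):
            bf.kosambi_inverse(-1.0)


class TestRecombinationEstimate:
    def _geno(self, col_a, col_b):
        df = pd.DataFrame({"A": col_a, "B": col_b},
                          index=[f"L{i}" for i in range(len(col_a))])
        return bf.GenotypeMatrix(df)

    def test_identical_columns_give_zero(self):
        g = self._geno(["OU", "AR", "OU"], ["OU", "AR", "OU"])
        est = bf.estimate_recombination_fraction(g, "A", "B")
        assert est.r == 0.0 and est.informative == 3

    def test_hand_counted_fixture(self):
        # 100 lines: 3 HET-excluded, 12 of the remaining 97 discordant
        a = ["OU"] * 100
        b = ["OU"] * 100
        for i in range(12):
            b[i] = "AR"
        for i in range(12, 15):
            a[i] = "HET"
        est = bf.estimate_recombination_fraction(self._geno(a, b), "A", "B")
        assert est.informative == 97 and est.recombinant == 12
        assert est.r == pytest.approx(12 / 97)

    def test_full_discordance_capped_below_half(self):
        g = self._geno(["OU", "OU"], ["AR", "AR"])
        est = bf.estimate_recombination_fraction(g, "A", "B")
        assert 0.49 < est.r < 0.5

    def test_no_informative_lines_error(self):
        g = self._geno(["HET", "NA"], ["OU", "AR"])
        with pytest.raises(UndefinedEstimateError):
            bf.estimate_recombination_fraction(g, "A", "B")


class TestImputation:
    def _map(self, positions):
        rows = [(f"M{i}", 1, p) for i, p in enumerate(positions)]
        return bf.GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))

    def test_marker_position_reproduces_observed_coding(self):
        m = self._map([0.0, 30.0])
        g = bf.GenotypeMatrix(pd.DataFrame(
            [["AR", "OU"], ["HET", "AR"]], index=["a", "b"], columns=["M0", "M1"]))
        d = bf.expected_dosages(g, m, [(1, 0.0), (1, 30.0)])
        np.testing.assert_allclose(d, [[1.0, -1.0], [0.0, 1.0]])

    def test_tight_linkage_midpoint_approaches_flank_genotype(self):
        m = self._map([0.0, 0.2])
        g = bf.GenotypeMatrix(pd.DataFrame([["OU", "OU"]], index=["a"],
                                           columns=["M0", "M1"]))
        d = bf.expected_dosages(g, m, [(1, 0.1)])[0, 0]
        assert d == pytest.approx(-1.0, abs=1e-3)

    @pytest.mark.parametrize("gL,gR", [(2, 0), (2, 2), (1, 0), (1, 1), (0, 0)])
    def test_midpoint_matches_monte_carlo_enumeration(self, gL, gR):
        m = self._map([0.0, 20.0])
        code = {0: "OU", 1: "HET", 2: "AR"}
        g = bf.GenotypeMatrix(pd.DataFrame([[code[gL], code[gR]]], index=["a"],
                                           columns=["M0", "M1"]))
        d = bf.expected_dosages(g, m, [(1, 10.0)])[0, 0]
        r = bf.kosambi_inverse(10.0)
        # rare flank pairs (e.g. AR/OU) leave few conditional draws, so use a
        # large draw count to keep the Monte Carlo error well below tolerance
        mc = mc_conditional_dosage(r, r, gL, gR, n_draws=4_000_000, seed=17)
        assert d == pytest.approx(mc, abs=0.02)

    def test_missing_call_conditions_on_nearest_nonmissing(self):
        m = self._map([0.0, 10.0, 20.0])
        g = bf.GenotypeMatrix(pd.DataFrame([["AR", "NA", "AR"]], index=["a"],
                                           columns=["M0", "M1", "M2"]))
        d = bf.expected_dosages(g, m, [(1, 10.0)])[0, 0]
        assert d > 0.9  # both non-missing flanks are donor homozygote

    def test_grid_covers_every_chromosome(self, small_map, small_genotypes):
        grid = bf.impute_pseudomarker_genotypes(small_genotypes, small_map, 2.0)
        assert set(grid.positions["chromosome"]) == {1, 2}
        assert np.all(np.abs(grid.dosages) <= 1 + 1e-9)
        # marker positions present in grid
        for c in (1, 2):
            gp = grid.positions.query("chromosome == @c")["pos_cm"].to_numpy()
            for p in small_map.positions_on(c):
                assert np.any(np.isclose(gp, p))


class TestCofactors:
    def test_perfect_signal_marker_selected_first(self, small_map, small_genotypes):
        y = small_genotypes.dosage()["M1_3"].fillna(0).to_numpy()
        cof = bf.select_cofactors(small_genotypes, small_map, y)
        assert "M1_3" in cof

    def test_pure_noise_selects_almost_nothing(self, small_map, small_genotypes):
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(small_genotypes.line_ids))
        cof = bf.select_cofactors(small_genotypes, small_map, y, entry_p=0.001)
        assert len(cof) <= 1

    def test_redundant_markers_resolved_by_map_order(self):
        rows = [("A", 1, 0.0), ("B", 1, 0.0), ("C", 1, 60.0)]
        m = bf.GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))
        g = bf.simulate_bil_genotypes(m, 60, seed=8)
        # A and B cosegregate exactly; signal on their shared dosage
        y = g.dosage()["A"].to_numpy() * 0.8
        cof = bf.select_cofactors(g, m, y)
        assert "A" in cof and "B" not in cof


class TestScan:
    def test_planted_marker_effect_recovered(self, small_map, small_genotypes):
        rng = np.random.default_rng(4)
        dose = small_genotypes.dosage()["M2_3"].fillna(0).to_numpy()
        y = 0.21 * dose + rng.normal(0, 0.01, dose.size)
        prof = bf.cim_scan(small_genotypes, small_map, y)
        peak = prof.table.loc[prof.table["lod"].idxmax()]
        assert peak["chromosome"] == 2
        assert abs(peak["pos_cm"] - 40.0) <= 2.0
        assert peak["additive_effect"] == pytest.approx(0.21, abs=0.01)

    def test_cofactor_excluded_inside_window(self, small_map, small_genotypes):
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(small_genotypes.line_ids))
        prof = bf.cim_scan(small_genotypes, small_map, y, cofactors=("M1_3",),
                           window_cm=10.0)
        tab = prof.table
        near = tab[(tab.chromosome == 1) & (np.abs(tab.pos_cm - 40.0) < 10.0)]
        far = tab[(tab.chromosome == 2)]
        assert (near["n_cofactors_used"] == 0).all()
        assert (far["n_cofactors_used"] == 1).all()

    def test_null_trait_profile_stays_low(self, small_map, small_genotypes):
        rng = np.random.default_rng(6)
        y = rng.normal(size=len(small_genotypes.line_ids))
        prof = bf.cim_scan(small_genotypes, small_map, y)
        assert (prof.table["lod"] >= 0).all()
        assert prof.table["lod"].max() < 5  # no signal planted

    def test_constant_trait_gives_zero_lod_and_threshold(self, small_map, small_genotypes):
        y = np.ones(len(small_genotypes.line_ids))
        prof = bf.cim_scan(small_genotypes, small_map, y)
        assert (prof.table["lod"] == 0).all()
        with pytest.warns(UserWarning):
            thr = bf.permutation_threshold(
                small_genotypes, small_map, y, bf.PermutationConfig(10, 0.05, 1))
        assert thr == 0.0


class TestPermutationThreshold:
    def test_quantile_matches_sorting_oracle(self):
        rng = np.random.default_rng(7)
        fake_max_lods = rng.gamma(2.0, 1.0, size=1000)
        assert empirical_quantile(fake_max_lods, 0.95) == pytest.approx(
            type7_quantile(fake_max_lods, 0.95), rel=1e-12)
        shuffled = rng.permutation(fake_max_lods)
        assert empirical_quantile(shuffled, 0.95) == empirical_quantile(fake_max_lods, 0.95)

    def test_threshold_reproducible_with_seed(self, small_map, small_genotypes):
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(small_genotypes.line_ids))
        pc = bf.PermutationConfig(50, 0.05, 123)
        t1 = bf.permutation_threshold(small_genotypes, small_map, y, pc)
        t2 = bf.permutation_threshold(small_genotypes, small_map, y, pc)
        assert t1 == t2 and t1 > 0


class TestCallQtl:
    def _sim_with_qtl(self, qtls, seed, n=104):
        m = bf.simulate_genetic_map(seed=seed)
        g = bf.simulate_bil_genotypes(m, n, seed=seed)
        truth = bf.SyntheticTruth(qtls=qtls, heritability=0.6)
        t = bf.simulate_trait(g, m, truth, seed=seed)
        return m, g, t

    def test_profile_below_threshold_yields_no_calls(self, small_map, small_genotypes):
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(small_genotypes.line_ids))
        prof = bf.cim_scan(small_genotypes, small_map, y)
        assert bf.call_qtl(prof, small_map, threshold=1e6) == []

    def test_two_planted_qtl_called_on_their_chromosomes(self):
        qtls = [Qtl(3, 40.0, 0.6), Qtl(8, 50.0, 0.6)]
        m, g, t = self._sim_with_qtl(qtls, seed=21)
        prof = bf.cim_scan(g, m, t)
        thr = bf.permutation_threshold(g, m, t, bf.PermutationConfig(100, 0.05, 2))
        calls = bf.call_qtl(prof, m, thr, "qSW")
        chroms = {c.chromosome for c in calls}
        assert {3, 8}.issubset(chroms)
        for c in calls:
            if c.chromosome in (3, 8):
                assert c.lod >= thr
                assert c.additive_effect > 0
                assert 0 <= c.r2_percent <= 100

    def test_eqtl_scan_shares_machinery_and_sign_convention(self):
        qtls = [Qtl(5, 30.0, 0.5)]
        m, g, t = self._sim_with_qtl(qtls, seed=22)
        y = t.means
        prof_t = bf.cim_scan(g, m, y)
        prof_e, thr, calls = bf.eqtl_scan(g, m, y, threshold=3.0)
        pd.testing.assert_frame_equal(prof_t.table, prof_e.table)
        # negative planted coupling flips the sign of the additive effect
        truth_neg = bf.SyntheticTruth(qtls=[Qtl(5, 30.0, -0.5)], heritability=0.8)
        t_neg = bf.simulate_trait(g, m, truth_neg, seed=23)
        prof_n, _, calls_n = bf.eqtl_scan(g, m, t_neg.means, threshold=3.0)
        assert all(c.additive_effect < 0 for c in calls_n if c.chromosome == 5)


class TestMapperEstimator:
    def test_fit_populates_attributes_and_calls(self):
        m = bf.simulate_genetic_map(seed=31)
        g = bf.simulate_bil_genotypes(m, 104, seed=31)
        truth = bf.SyntheticTruth(qtls=[Qtl(2, 50.0, 0.7)], heritability=0.7)
        t = bf.simulate_trait(g, m, truth, seed=31)
        mapper = bf.CompositeIntervalMapper(
            genetic_map=m, use_cofactors=False, n_permutations=60, random_state=1
        ).fit(g, t)
        assert mapper.threshold_ > 0
        assert not mapper.lod_profile_.table.empty
        assert any(c.chromosome == 2 for c in mapper.qtl_)
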