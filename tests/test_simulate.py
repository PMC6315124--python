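"""Synthetic BIL generator: pedigree expectations, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest

import bilfreqsel as bf
from bilfreqsel.datatypes import InvalidParameterError, ParseError, ValidationError


class TestGeneticMap:
    def test_default_map_has_124_markers_on_12_chromosomes(self):
        m = bf.simulate_genetic_map(seed=1)
        assert len(m.markers) == 124
        assert len(m.chromosomes) == 12
        for c in m.chromosomes:
            pos = m.positions_on(c)
            assert np.all(np.diff(pos) >= 0)
            assert pos[0] == 0.0

    def test_two_marker_chromosome_uses_endpoints(self):
        m = bf.simulate_genetic_map(1, (2,), (100.0,), seed=3)
        assert list(m.positions_on(1)) == [0.0, 100.0]

    def test_same_seed_reproduces_map_exactly(self):
        a = bf.simulate_genetic_map(seed=7).table
        b = bf.simulate_genetic_map(seed=7).table
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chromosomes": 0},
            {"chromosome_lengths_cm": (0.0,), "n_chromosomes": 1, "markers_per_chromosome": (3,)},
            {"markers_per_chromosome": (1,), "n_chromosomes": 1, "chromosome_lengths_cm": (50.0,)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            bf.simulate_genetic_map(**kwargs)


class TestBilGenotypes:
    def test_donor_dosage_matches_backcross_expectation(self, small_map):
        n = 10_000
        g = bf.simulate_bil_genotypes(small_map, n, 1, 0, seed=2)
        frac = (g.donor_counts().to_numpy() / 2).mean()
        # BC1: donor allele frequency 1/4; binomial-ish SE at marker level
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se * 3  # markers are correlated: be generous

    def test_heterozygosity_decays_with_selfing(self, small_map):
        n = 10_000
        g = bf.simulate_bil_genotypes(small_map, n, 1, 5, seed=2)
        het = (g.donor_counts().to_numpy() == 1).mean()
        expect = 0.5 / 32
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(het - expect) < 3 * se * 3

    def test_zero_distance_markers_cosegregate(self):
        rows = [("A", 1, 0.0), ("B", 1, 0.0), ("C", 1, 50.0)]
        m = bf.GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))
        g = bf.simulate_bil_genotypes(m, 500, seed=4)
        assert (g.calls["A"] == g.calls["B"]).all()

    def test_single_meiosis_recombination_matches_kosambi_inverse(self, small_map):
        # In BC1 without selfing the donor haplotype is directly observable,
        # so adjacent-marker switch rates estimate the gamete-level r.
        n = 10_000
        g = bf.simulate_bil_genotypes(small_map, n, 1, 0, seed=9)
        h = (g.donor_counts()[small_map.markers_on(1)].to_numpy() == 1).astype(int)
        pos = small_map.positions_on(1)
        for j in range(len(pos) - 1):
            r_expected = bf.kosambi_inverse(pos[j + 1] - pos[j])
            r_obs = np.mean(h[:, j] != h[:, j + 1])
            se = np.sqrt(r_expected * (1 - r_expected) / n)
            assert abs(r_obs - r_expected) < 4 * se

    def test_determinism_and_missing_codes(self, small_map):
        a = bf.simulate_bil_genotypes(small_map, 50, seed=1, missing_rate=0.05)
        b = bf.simulate_bil_genotypes(small_map, 50, seed=1, missing_rate=0.05)
        pd.testing.assert_frame_equal(a.calls, b.calls)
        assert (a.calls.to_numpy() == "NA").any()


class TestTrait:
    def test_homozygote_difference_is_twice_additive_effect(self, small_map):
        truth = bf.SyntheticTruth(
            qtls=[bf.datatypes.Qtl(1, 40.0, 0.7)], heritability=None, trait_noise_sd=0.0
        )
        calls = pd.DataFrame(
            [["AR"] * 11, ["OU"] * 11],
            index=["hiAR", "hiOU"],
            columns=small_map.markers,
        )
        g = bf.GenotypeMatrix(calls)
        t = bf.simulate_trait(g, small_map, truth, seed=0)
        diff = t.means["hiAR"] - t.means["hiOU"]
        assert diff == pytest.approx(2 * 0.7, abs=1e-12)

    def test_parental_means_match_defaults(self, study_map):
        truth = bf.default_truth(100, 4)
        truth.heritability = None
        truth.trait_noise_sd = 0.0
        parents = bf.parental_genotypes(study_map)
        t = bf.simulate_trait(parents, study_map, truth, seed=0)
        # interior QTL dosages are flank-conditioned expectations, which admit
        # a small double-crossover probability even in pure parents
        assert t.means["Ouu365"] == pytest.approx(2.91, abs=0.02)
        assert t.means["ArrozDaTerra"] == pytest.approx(5.11, abs=0.02)

    def test_high_heritability_gives_near_perfect_genetic_r2(self, small_map):
        truth = bf.SyntheticTruth(
            qtls=[bf.datatypes.Qtl(1, 20.0, 0.5), bf.datatypes.Qtl(2, 40.0, -0.4)],
            heritability=0.999,
        )
        g = bf.simulate_bil_genotypes(small_map, 1000, seed=3)
        t = bf.simulate_trait(g, small_map, truth, seed=3)
        dose = bf.expected_dosages(g, small_map, [(1, 20.0), (2, 40.0)])
        X = np.column_stack([np.ones(len(dose)), dose])
        y = t.means.loc[g.line_ids].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.98

    def test_bad_heritability_rejected(self):
        with pytest.raises(InvalidParameterError):
            bf.SyntheticTruth(heritability=1.5)


class TestExpression:
    def test_null_genes_uncorrelated_with_trait(self, small_map):
        truth = bf.SyntheticTruth(qtls=[], causal_genes={}, heritability=None,
                                  trait_noise_sd=0.5, near_zero_fraction=0.0)
        g = bf.simulate_bil_genotypes(small_map, 22, seed=5)
        t = bf.simulate_trait(g, small_map, truth, seed=5)
        e = bf.simulate_expression(g, small_map, t, 400, truth, seed=5)
        log2x = np.log2(e.values.to_numpy() + 0.01)
        y = t.means.loc[e.sample_ids].to_numpy()
        rs = [np.corrcoef(row, y)[0, 1] for row in log2x]
        assert abs(np.mean(rs)) < 0.03

    def test_planted_gene_strongly_correlated(self, small_map):
        truth = bf.SyntheticTruth(
            qtls=[], causal_genes={"gene_00005": 2.0}, heritability=None,
            trait_noise_sd=0.5, expression_noise_sd_log2=0.1, near_zero_fraction=0.0,
        )
        g = bf.simulate_bil_genotypes(small_map, 22, seed=6)
        t = bf.simulate_trait(g, small_map, truth, seed=6)
        e = bf.simulate_expression(g, small_map, t, 100, truth, seed=6)
        y = t.means.loc[e.sample_ids].to_numpy()
        r = np.corrcoef(np.log2(e.values.loc["gene_00005"] + 0.01), y)[0, 1]
        assert abs(r) > 0.9

    def test_near_zero_fraction_removed_by_filter(self, small_map):
        truth = bf.SyntheticTruth(qtls=[], causal_genes={}, heritability=None,
                                  trait_noise_sd=0.5, near_zero_fraction=0.10)
        g = bf.simulate_bil_genotypes(small_map, 22, seed=7)
        t = bf.simulate_trait(g, small_map, truth, seed=7)
        e = bf.simulate_expression(g, small_map, t, 5000, truth, seed=7)
        kept = bf.filter_low_expression(e)
        removed = 5000 - kept.values.shape[0]
        assert 450 <= removed <= 600  # ~10% planted near-silent plus rare low draws


class TestRoundTrip:
    def test_dataset_round_trip_identity(self, tmp_path):
        ds, fresh = bf.simulate_dataset(seed=2, n_lines=20, n_rnaseq_lines=5,
                                        n_genes=60, truth=bf.default_truth(60, 4))
        bf.write_dataset(ds, tmp_path / "d", fresh_trait=fresh)
        back = bf.read_dataset(tmp_path / "d")
        pd.testing.assert_frame_equal(ds.genetic_map.table, back.genetic_map.table,
                                      check_dtype=False)
        pd.testing.assert_frame_equal(ds.genotypes.calls, back.genotypes.calls,
                                      check_names=False)
        np.testing.assert_allclose(ds.expression.values, back.expression.values,
                                   rtol=1e-9)
        np.testing.assert_allclose(
            ds.trait.means.to_numpy(), back.trait.means.to_numpy(), rtol=1e-9
        )
        assert back.truth.to_dict() == ds.truth.to_dict()

    def test_illegal_genotype_code_raises_parse_error(self, tmp_path):
        p = tmp_path / "genotypes.tsv"
        p.write_text("line_id\tM1\tM2\nL1\tOU\tXX\n")
        with pytest.raises(ParseError, match="XX"):
            bf.simulate.read_genotypes(p)

    def test_empty_expression_matrix_rejected(self, tmp_path):
        p = tmp_path / "expression.tsv"
        p.write_text("gene_id\n")
        with pytest.raises((ParseError, ValidationError)):
            bf.simulate.read_expression(p)
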