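"""Tests of the F2 cross / bulk / pooled-sequencing simulator."""
import numpy as np
import pytest
from scipy import stats

import bulkscan as bs

from conftest import single_chrom_map


class TestGeneticMap:
    def test_default_design_has_2259_markers(self, cucumber_genome):
        gmap = bs.simulate_genetic_map(cucumber_genome)
        assert gmap.n_markers == 2259
        per_chrom = gmap.df.groupby("chrom", sort=False).size().tolist()
        assert per_chrom == list(bs.CUCUMBER_MARKERS_PER_CHROMOSOME)

    def test_two_markers_sit_at_chromosome_ends(self):
        genome = bs.GenomeModel([bs.ChromosomeSpec("c", 1_000_000, 100.0)])
        gmap = bs.simulate_genetic_map(genome, [2])
        assert gmap.df["pos_bp"].tolist() == [1, 1_000_000]
        assert gmap.df["pos_cm"].tolist() == [0.0, 100.0]

    def test_same_seed_gives_identical_map(self, cucumber_genome):
        a = bs.simulate_genetic_map(cucumber_genome, seed=3, placement="uniform")
        b = bs.simulate_genetic_map(cucumber_genome, seed=3, placement="uniform")
        assert a.df.equals(b.df)

    def test_genetic_positions_proportional_to_physical(self, cucumber_genome):
        gmap = bs.simulate_genetic_map(cucumber_genome)
        chr2 = gmap.chrom_view("chr2")
        frac_bp = (chr2["pos_bp"] - 1) / (bs.CUCUMBER_CHROMOSOME_LENGTHS["chr2"] - 1)
        frac_cm = chr2["pos_cm"] / chr2["pos_cm"].max()
        np.testing.assert_allclose(frac_bp, frac_cm, atol=1e-9)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            bs.ChromosomeSpec("c", 0, 10.0)

    def test_unsorted_map_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            single_chrom_map([100, 50], [0.0, 5.0])


class TestF2Simulation:
    def test_single_marker_segregates_1_2_1(self):
        gmap = single_chrom_map([1000], [0.0])
        pop = bs.simulate_f2(gmap, 10_000, seed=5)
        counts = np.bincount(pop.genotypes[:, 0], minlength=3)
        chi2 = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        assert chi2.pvalue > 0.001

    def test_zero_recombination_copies_genotypes(self):
        gmap = single_chrom_map([100, 200], [0.0, 1e-9])
        pop = bs.simulate_f2(gmap, 500, seed=2)
        np.testing.assert_array_equal(pop.genotypes[:, 0], pop.genotypes[:, 1])

    def test_distant_markers_recombine_freely(self):
        gmap = single_chrom_map([100, 90_000_000], [0.0, 500.0])
        pop = bs.simulate_f2(gmap, 5000, seed=9)
        r_hat = bs.estimate_r_f2(pop.genotypes[:, 0], pop.genotypes[:, 1])
        assert abs(r_hat - 0.5) < 0.05

    def test_adjacent_marker_recombination_matches_map(self):
        d_cm = bs.kosambi_cm(0.1)
        gmap = single_chrom_map([1, 1_000_000], [0.0, d_cm])
        pop = bs.simulate_f2(gmap, 2000, seed=4)
        r_hat = bs.estimate_r_f2(pop.genotypes[:, 0], pop.genotypes[:, 1])
        se = np.sqrt(0.1 * 0.9 / (2 * 2000))
        assert abs(r_hat - 0.1) < 3 * se

    def test_seed_reproducibility(self, tiny_map):
        a = bs.simulate_f2(tiny_map, 100, seed=7)
        b = bs.simulate_f2(tiny_map, 100, seed=7)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)


class TestPhenotype:
    def test_noise_free_genotype_means(self, tiny_map):
        """With residual_sd = 0 the phenotype is exactly mu + a*x + d*z."""
        pop = bs.F2Population(np.array([[2, 2], [1, 1], [0, 0]]))
        qtl = bs.QTLSpec(chromosome="chr1", position_bp=1, residual_sd=0.0)
        y = bs.simulate_phenotype(pop, qtl, tiny_map, seed=0)
        np.testing.assert_allclose(y, [24.2, 20.1, 13.3])

    def test_null_qtl_phenotype_independent_of_genotype(self, tiny_map):
        pop = bs.simulate_f2(tiny_map, 4000, seed=1)
        qtl = bs.QTLSpec(chromosome="chr1", position_bp=1,
                         additive=0.0, dominance=0.0, residual_sd=2.0)
        y = bs.simulate_phenotype(pop, qtl, tiny_map, seed=1)
        r = np.corrcoef(pop.genotypes[:, 0], y)[0, 1]
        assert abs(r) < 0.05

    def test_residual_sd_solves_variance_fraction(self, tiny_map):
        """The closed-form residual SD yields the requested QTL R^2."""
        sd = bs.residual_sd_for_r2(5.45, 1.35, 0.4257)
        pop = bs.simulate_f2(tiny_map, 60_000, seed=3)
        qtl = bs.QTLSpec(chromosome="chr1", position_bp=1, residual_sd=sd)
        y = bs.simulate_phenotype(pop, qtl, tiny_map, seed=3)
        code = pop.genotypes[:, 0].astype(float)
        g = 18.75 + 5.45 * (code - 1) + 1.35 * (code == 1)
        r2_emp = np.var(g) / np.var(y)
        assert abs(r2_emp - 0.4257) < 0.02


class TestBulkSelection:
    def test_extremes_selected_by_value(self):
        high, low = bs.select_bulks(np.arange(1.0, 11.0), 2)
        assert set(high) == {8, 9}   # values 9, 10
        assert set(low) == {0, 1}    # values 1, 2

    def test_all_ties_first_last_blocks(self):
        high, low = bs.select_bulks(np.ones(10), 3)
        assert low.tolist() == [0, 1, 2]
        assert high.tolist() == [7, 8, 9]

    def test_bulks_disjoint_and_sized(self, default_cross):
        high, low = default_cross.high_indices, default_cross.low_indices
        assert len(high) == len(low) == 50
        assert not set(high) & set(low)

    def test_high_bulk_emulates_thick_flesh_pool(self, default_cross):
        """High/low bulk means bracket the parental phenotype extremes."""
        phen = default_cross.phenotypes
        assert phen[default_cross.high_indices].mean() > 22.9
        assert phen[default_cross.low_indices].mean() < 12.6
        assert phen[default_cross.high_indices].min() > phen[default_cross.low_indices].max()

    def test_invalid_bulk_size(self):
        with pytest.raises(ValueError):
            bs.select_bulks(np.arange(10.0), 0)
        with pytest.raises(ValueError):
            bs.select_bulks(np.arange(10.0), 6)


class TestBulkCounts:
    def _counts(self, codes, error_rate=0.0):
        gmap = single_chrom_map([1000], [0.0])
        pop = bs.F2Population(np.array(codes).reshape(-1, 1))
        n = pop.n
        return bs.simulate_bulk_counts(
            pop, np.arange(n), np.arange(n), gmap,
            depth=bs.DepthModel(40.0, None, error_rate), seed=0,
        )

    def test_fixed_high_parent_bulk_gives_only_ref_reads(self):
        table = self._counts([[2]] * 6)
        assert (table.df["high_bulk_alt"] == 0).all()
        assert (table.df["high_bulk_ref"] > 0).all()

    def test_fixed_low_parent_bulk_gives_no_ref_reads(self):
        table = self._counts([[0]] * 6)
        assert (table.df["high_bulk_ref"] == 0).all()

    def test_mean_depth_matches_model(self):
        gmap = single_chrom_map(
            np.arange(1, 10_001) * 100, np.linspace(0, 100, 10_000)
        )
        pop = bs.simulate_f2(gmap, 40, seed=8)
        table = bs.simulate_bulk_counts(
            pop, np.arange(20), np.arange(20, 40), gmap,
            depth=bs.DepthModel(48.86, 8.0, 0.001), seed=8,
        )
        depth = table.df["high_bulk_ref"] + table.df["high_bulk_alt"]
        assert abs(depth.mean() - 48.86) / 48.86 < 0.02

    def test_bulk_divergence_monotone_in_additive_effect(self, cucumber_genome):
        """|allele-frequency contrast| at the QTL grows with the QTL effect."""
        div = []
        for a in (0.0, 1.0, 2.5, 5.45):
            qtl = bs.QTLSpec(additive=a, dominance=0.0,
                             residual_sd=bs.QTLSpec().residual_sd)
            sim = bs.simulate_cross(qtl=qtl, seed=42)
            j = sim.gmap.nearest_marker("chr2", 4_500_000)
            p_high = sim.population.genotypes[sim.high_indices, j].mean() / 2
            p_low = sim.population.genotypes[sim.low_indices, j].mean() / 2
            div.append(abs(p_high - p_low))
        assert all(b >= a - 0.02 for a, b in zip(div, div[1:]))
        assert div[-1] > div[0] + 0.3


def test_genetic_variance_closed_form():
    """Var(a*x + d*z) under 1:2:1 equals a^2/2 + d^2/4 (checked by enumeration)."""
    a, d = 5.45, 1.35
    codes = np.array([0, 1, 1, 2], dtype=float)  # exact 1:2:1 weights
    g = a * (codes - 1) + d * (codes == 1)
    assert np.isclose(np.var(g), bs.genetic_variance(a, d))


def test_simulate_cross_reproducible():
    a = bs.simulate_cross(seed=5, n=100, bulk_size=10)
    b = bs.simulate_cross(seed=5, n=100, bulk_size=10)
    assert a.markers == b.markers
    np.testing.assert_array_equal(a.phenotypes, b.phenotypes)
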