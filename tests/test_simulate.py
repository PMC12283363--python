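"""Simulator behaviour: renewal-process counts, thinning, maps, populations."""

import numpy as np
import pytest

from xomap import (
    ChromosomeSpec,
    ObservationModel,
    RecombinationModel,
    build_population,
    simulate_bivalent_crossovers,
    summarize_meiocyte,
    thin_to_chromatid,
    uniform_marker_panel,
)
from xomap.matrix import HET, HOM_COL, MISSING
from xomap.simulate import true_genotypes


def counts_of(spec, lam, nu, n, rng, obligate=False):
    return np.array(
        [len(simulate_bivalent_crossovers(spec, lam, nu, rng, obligate)) for _ in range(n)]
    )


class TestBivalentCrossovers:
    def test_zero_rate_is_empty(self, small_spec, rng):
        assert len(simulate_bivalent_crossovers(small_spec, 0.0, 5, rng)) == 0

    def test_nu1_matches_poisson_mean_and_dispersion(self, small_spec, rng):
        n = 10_000
        c = counts_of(small_spec, 2.0, 1, n, rng)
        # Poisson(2): mean 2, index of dispersion 1
        se_mean = np.sqrt(2.0 / n)
        assert abs(c.mean() - 2.0) < 3 * se_mean
        disp = c.var() / c.mean()
        # var of dispersion index for Poisson ~ 2/(n-1)
        assert abs(disp - 1.0) < 3 * np.sqrt(2.0 / (n - 1))

    def test_nu1_count_distribution_is_poisson(self, small_spec, rng):
        from scipy import stats

        c = counts_of(small_spec, 2.0, 1, 10_000, rng)
        kmax = c.max()
        obs = np.bincount(c, minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), 2.0) * len(c)
        # pool the sparse tail so expected counts stay >= 5
        while exp[-1] < 5 and len(exp) > 2:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        exp = exp * obs.sum() / exp.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01

    def test_interference_gives_subpoisson_counts(self, small_spec, rng):
        c = counts_of(small_spec, 2.0, 5, 10_000, rng)
        assert c.var() / c.mean() < 1.0

    def test_positions_sorted_within_genetic_length(self, small_spec, rng):
        for _ in range(50):
            pos = simulate_bivalent_crossovers(small_spec, 3.0, 2, rng)
            assert np.all(np.diff(pos) > 0)
            assert np.all((pos >= 0) & (pos <= small_spec.genetic_length_cM))

    def test_non_integer_nu_rejected(self, small_spec, rng):
        with pytest.raises(ValueError, match="integer"):
            simulate_bivalent_crossovers(small_spec, 2.0, 2.5, rng)
        with pytest.raises(ValueError, match="integer"):
            RecombinationModel(sex="male", lambda_biv={"chrS": 2.0}, nu=0)

    def test_obligate_co_never_emits_zero(self, small_spec, rng):
        c = counts_of(small_spec, 0.5, 1, 2000, rng, obligate=True)
        assert c.min() >= 1
        # conditioning on >=1 inflates the mean above lambda
        assert c.mean() > 0.5


class TestThinning:
    def test_empty_input(self, rng):
        assert len(thin_to_chromatid([], rng)) == 0

    def test_halves_mean_genome_wide(self, small_spec, rng):
        # bivalent mean 9.6 -> transmitted mean 4.8
        n = 10_000
        trans = np.array(
            [len(thin_to_chromatid(np.sort(rng.uniform(0, 60, rng.poisson(9.6))), rng)) for _ in range(n)]
        )
        assert abs(trans.mean() - 4.8) < 3 * trans.std() / np.sqrt(n)

    def test_single_co_retained_half_the_time(self, rng):
        kept = np.array([len(thin_to_chromatid([10.0], rng)) for _ in range(10_000)])
        assert set(kept) <= {0, 1}
        p = kept.mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_preserves_interference_sign(self, small_spec, rng):
        # sub-Poisson bivalent counts stay sub-Poisson after thinning
        c = np.array(
            [
                len(thin_to_chromatid(simulate_bivalent_crossovers(small_spec, 4.0, 5, rng), rng))
                for _ in range(10_000)
            ]
        )
        assert c.var() / c.mean() < 1.0


class TestGeneticPhysicalMap:
    def test_linear_midpoint(self):
        spec = ChromosomeSpec("c", 1_000_000, map_points=((1, 0.0), (1_000_000, 50.0)))
        assert abs(spec.genetic_to_physical(25.0) - 500_000) <= 1

    def test_boundaries(self):
        spec = ChromosomeSpec("c", 1_000_000, map_points=((1, 0.0), (1_000_000, 50.0)))
        assert spec.genetic_to_physical(0.0) == 1
        assert spec.genetic_to_physical(50.0) == 1_000_000

    def test_round_trip_identity(self, tair_specs, rng):
        spec = tair_specs[0]
        bp = rng.integers(1, spec.length_bp + 1, size=100)
        back = spec.genetic_to_physical(spec.physical_to_genetic(bp))
        assert np.all(np.abs(back - bp) <= 1)

    def test_out_of_range_rejected(self, small_spec):
        with pytest.raises(ValueError):
            small_spec.genetic_to_physical(small_spec.genetic_length_cM + 1)
        with pytest.raises(ValueError):
            small_spec.physical_to_genetic(0)

    def test_invalid_anchor_sets_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeSpec("c", 100, map_points=((1, 0.0), (50, 1.0)))  # last != length
        with pytest.raises(ValueError):
            ChromosomeSpec("c", 100, map_points=((1, 0.5), (100, 1.0)))  # first cM != 0


class TestMeiocyteSummary:
    def test_no_univalents(self):
        s = summarize_meiocyte((2, 1, 1, 3, 2))
        assert s.n_univalent_pairs == 0 and s.n_bivalents == 5

    def test_with_univalents(self):
        s = summarize_meiocyte((0, 0, 1, 2, 1))
        assert s.n_univalent_pairs == 2 and s.n_bivalents == 3

    def test_univalent_frequency_matches_poisson_zero_class(self, tair_specs, rng):
        # nu=1, lambda=2.4 each chromosome: P(>=1 univalent pair) = 1-(1-e^-2.4)^5
        n = 10_000
        lam = 2.4
        any_uni = 0
        for _ in range(n):
            counts = [
                len(simulate_bivalent_crossovers(spec, lam, 1, rng)) for spec in tair_specs
            ]
            any_uni += summarize_meiocyte(counts).n_univalent_pairs > 0
        p_hat = any_uni / n
        p_exp = 1 - (1 - np.exp(-lam)) ** 5
        assert abs(p_hat - p_exp) < 3 * np.sqrt(p_exp * (1 - p_exp) / n)


class TestBuildPopulation:
    def panel(self, specs, rng, n=200):
        return uniform_marker_panel(specs, n_per_chrom=n, rng=rng)

    def test_zero_noise_observation_is_identity(self, tair_specs, rng):
        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        obs = ObservationModel(depth_mean=50.0)  # P(depth 0) negligible at 50x
        gm, truths, _ = build_population(20, tair_specs, model, self.panel(tair_specs, rng), obs, seed=7)
        for i, t in enumerate(truths):
            assert np.array_equal(gm.calls[i], true_genotypes(t, gm.markers))

    def test_het_frequency_near_quarter_allele_frequency(self, tair_specs, rng):
        from xomap.qc import ler_allele_frequency

        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        obs = ObservationModel(depth_mean=50.0)
        gm, _, _ = build_population(1000, tair_specs, model, self.panel(tair_specs, rng), obs, seed=11)
        freq = ler_allele_frequency(gm.calls)
        # markers share the same gametes, so the replication unit for the
        # 3-s.e. check is the sample: per-sample Ler allele fraction ~ 0.25
        per_sample = 0.5 * (gm.calls == HET).mean(axis=1)
        se = per_sample.std() / np.sqrt(gm.n_samples)
        assert abs(per_sample.mean() - 0.25) < 3 * se
        # and the typical marker passes the BC1 MAF window
        assert 0.2 < np.median(freq) < 0.3

    def test_truth_mean_transmitted_cos(self, tair_specs, rng):
        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        obs = ObservationModel(depth_mean=50.0)
        gm, truths, _ = build_population(1000, tair_specs, model, self.panel(tair_specs, rng), obs, seed=13)
        n_cos = np.array([t.n_cos() for t in truths])
        assert abs(n_cos.mean() - 4.8) < 3 * n_cos.std() / np.sqrt(len(n_cos))

    def test_deterministic_from_seed(self, tair_specs, rng):
        model = RecombinationModel.from_transmitted_mean(tair_specs, 3.0, nu=2)
        obs = ObservationModel(depth_mean=1.2, e_hom_ler=0.05)
        panel = self.panel(tair_specs, np.random.default_rng(5))
        a = build_population(30, tair_specs, model, panel, obs, seed=99)
        b = build_population(30, tair_specs, model, panel, obs, seed=99)
        assert np.array_equal(a[0].calls, b[0].calls)
        assert np.array_equal(a[0].depth, b[0].depth)
        for ta, tb in zip(a[1], b[1]):
            for c in ta.co_bp:
                assert np.array_equal(ta.co_bp[c], tb.co_bp[c])

    def test_empty_panel_rejected(self, tair_specs):
        import pandas as pd

        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        with pytest.raises(ValueError, match="panel"):
            build_population(5, tair_specs, model, pd.DataFrame(), ObservationModel(), seed=1)

    def test_read_based_het_dropout_at_depth_one(self, tair_specs, rng):
        """A HET covered by one read is observed HOM_COL or HOM_LER, ~50/50."""
        from xomap.matrix import HOM_LER

        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        obs = ObservationModel(depth_mean=1.0, read_based_het_calls=True)
        gm, truths, _ = build_population(200, tair_specs, model, self.panel(tair_specs, rng), obs, seed=3)
        truth = np.vstack([true_genotypes(t, gm.markers) for t in truths])
        het_d1 = (truth == HET) & (gm.depth == 1)
        observed = gm.calls[het_d1]
        assert set(np.unique(observed)) <= {int(HOM_COL), int(HOM_LER)}
        frac_col = (observed == HOM_COL).mean()
        assert abs(frac_col - 0.5) < 3 * np.sqrt(0.25 / len(observed))
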