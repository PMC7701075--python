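"""Tests for weighted-distribution machinery and the l <-> s mapping."""

import numpy as np
import pytest

from fibrilhydro import (
    FibrilMaterial,
    SolventConditions,
    convert_weighting,
    fit_lognormal,
    fit_weibull,
    ingest_length_table,
    length_dist_to_s_dist,
    s_dist_to_length_dist,
    sedimentation_coefficient_svedberg,
    summarize,
)
from fibrilhydro.distribution_engine import WeightedDistribution
from fibrilhydro.fixtures import generate_afm_lengths


def lognormal_pdf(x, median, shape):
    return np.exp(-((np.log(x) - np.log(median)) ** 2) / (2 * shape**2)) / (
        x * shape * np.sqrt(2 * np.pi)
    )


def weibull_pdf(x, shape, scale):
    z = x / scale
    return (shape / scale) * z ** (shape - 1) * np.exp(-(z**shape))


def cdf_at(dist, x):
    c = dist.cumulative()
    return np.interp(x, dist.grid, c / c[-1])


class TestIngest:
    def test_filter_and_counting(self):
        dist = ingest_length_table([40.0, 100.0, 100.0, 300.0], bins=None)
        assert dist.metadata["n_removed"] == 1
        np.testing.assert_allclose(dist.grid, [100.0, 300.0])
        np.testing.assert_allclose(dist.density, [2 / 3, 1 / 3])
        assert dist.weighting == "number"

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError, match="minimum-length"):
            ingest_length_table([10.0, 20.0, 49.9])

    def test_binned_lognormal_sample_recovers_mean(self):
        lengths = generate_afm_lengths(n=2000, seed=42)
        dist = ingest_length_table(lengths, bins=64)
        assert dist.integral() == pytest.approx(1.0, abs=1e-12)
        fit = fit_lognormal(dist)
        assert fit.mean == pytest.approx(395.0, rel=0.05)


class TestWeightingConversion:
    def test_number_to_mass_is_length_proportional(self):
        dist = WeightedDistribution(
            "length", np.array([100.0, 300.0]), np.array([0.5, 0.5]), "number",
            discrete=True,
        )
        mass = convert_weighting(dist, "mass")
        np.testing.assert_allclose(mass.density, [0.25, 0.75])

    def test_extinction_equals_mass(self, lognormal_length_dist):
        ext = convert_weighting(lognormal_length_dist, "extinction")
        np.testing.assert_allclose(ext.density, lognormal_length_dist.normalized().density)

    def test_round_trip_identity(self, lognormal_length_dist):
        num = convert_weighting(lognormal_length_dist, "number")
        back = convert_weighting(num, "mass")
        ref = lognormal_length_dist.normalized()
        assert np.max(np.abs(back.density - ref.density)) <= 1e-12 * ref.density.max()

    def test_unknown_weighting_rejected(self, lognormal_length_dist):
        with pytest.raises(ValueError, match="weighting"):
            convert_weighting(lognormal_length_dist, "volume")

    def test_s_axis_requires_lengths(self, lognormal_length_dist, material, solvent):
        sdist = length_dist_to_s_dist(lognormal_length_dist, 4.7, material, solvent)
        with pytest.raises(ValueError, match="lengths"):
            convert_weighting(sdist, "number")


class TestFits:
    def test_lognormal_self_consistency(self):
        grid = np.linspace(50.0, 1500.0, 200)
        dens = lognormal_pdf(grid, 400.0, 0.3)
        dist = WeightedDistribution("length", grid, dens, "mass")
        fit = fit_lognormal(dist)
        assert fit.median == pytest.approx(400.0, rel=1e-6)
        assert fit.shape == pytest.approx(0.3, rel=1e-6)

    def test_weibull_self_consistency(self):
        grid = np.linspace(0.5, 120.0, 200)
        dens = weibull_pdf(grid, 2.0, 30.0)
        dist = WeightedDistribution("sedimentation_coefficient", grid, dens, "extinction")
        fit = fit_weibull(dist)
        assert fit.shape == pytest.approx(2.0, rel=1e-6)
        assert fit.scale == pytest.approx(30.0, rel=1e-6)

    def test_weibull_with_seeded_noise(self):
        grid = np.linspace(0.5, 120.0, 200)
        dens = weibull_pdf(grid, 2.0, 30.0)
        rng = np.random.default_rng(7)
        noisy = np.clip(dens + rng.normal(0, 0.02 * dens.max(), dens.size), 0, None)
        dist = WeightedDistribution("sedimentation_coefficient", grid, noisy, "extinction")
        fit = fit_weibull(dist)
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.scale == pytest.approx(30.0, rel=0.05)

    def test_too_few_points_raises(self):
        dist = WeightedDistribution(
            "length", np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4), "number"
        )
        with pytest.raises(ValueError, match="at least 5"):
            fit_lognormal(dist)


class TestMapping:
    def test_delta_maps_to_forward_model(self, material, solvent):
        delta = WeightedDistribution(
            "length", np.array([500.0]), np.array([1.0]), "mass", discrete=True
        )
        sdist = length_dist_to_s_dist(delta, 4.7, material, solvent)
        expect = float(sedimentation_coefficient_svedberg(500.0, 4.7, material, solvent))
        assert sdist.grid[0] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(33.5, abs=0.1)

    def test_delta_inverse(self, material, solvent):
        delta = WeightedDistribution(
            "sedimentation_coefficient", np.array([33.46184962187084]),
            np.array([1.0]), "mass", discrete=True,
        )
        ldist = s_dist_to_length_dist(delta, 4.7, material, solvent)
        assert ldist.grid[0] == pytest.approx(500.0, rel=1e-6)

    def test_weight_conserved(self, lognormal_length_dist, material, solvent):
        sdist = length_dist_to_s_dist(lognormal_length_dist, 4.7, material, solvent)
        assert sdist.integral() == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_cdf(self, lognormal_length_dist, material, solvent):
        sdist = length_dist_to_s_dist(lognormal_length_dist, 4.7, material, solvent)
        back = s_dist_to_length_dist(sdist, 4.7, material, solvent)
        ref = lognormal_length_dist.normalized()
        x = np.linspace(ref.grid[0], ref.grid[-1], 400)
        assert np.max(np.abs(cdf_at(back, x) - cdf_at(ref, x))) <= 1e-6

    def test_quantiles_equivariant(self, lognormal_length_dist, material, solvent):
        sdist = length_dist_to_s_dist(lognormal_length_dist, 4.7, material, solvent)
        for p in (0.1, 0.5, 0.9):
            ql = float(lognormal_length_dist.normalized().quantile(p))
            qs = float(sdist.quantile(p))
            mapped = float(sedimentation_coefficient_svedberg(ql, 4.7, material, solvent))
            assert qs == pytest.approx(mapped, rel=2e-3)

    def test_out_of_range_s_excluded(self, material, solvent):
        grid = np.linspace(0.5, 60.0, 120)  # includes s below the rod limit
        dens = np.ones_like(grid)
        dist = WeightedDistribution(
            "sedimentation_coefficient", grid, dens, "mass"
        ).normalized()
        ldist = s_dist_to_length_dist(dist, 4.7, material, solvent)
        assert ldist.metadata["excluded_fraction"] > 0
        assert ldist.integral() == pytest.approx(1.0, abs=1e-9)

    def test_commutes_with_weighting_conversion(
        self, lognormal_length_dist, material, solvent
    ):
        a = length_dist_to_s_dist(
            convert_weighting(lognormal_length_dist, "number"), 4.7, material, solvent
        )
        b_s = length_dist_to_s_dist(lognormal_length_dist, 4.7, material, solvent)
        lengths = lognormal_length_dist.grid
        b = convert_weighting(b_s, "number", lengths_nm=lengths)
        assert np.max(np.abs(a.density - b.density)) <= 1e-8 * a.density.max()


class TestSummarize:
    def test_symmetric_triangle(self):
        grid = np.linspace(0.01, 2.0, 401)
        dens = 1.0 - np.abs(grid - 1.0)
        dens = np.clip(dens, 0, None)
        dist = WeightedDistribution("length", grid, dens, "number")
        s = summarize(dist)
        assert s.mode == pytest.approx(1.0, abs=0.01)
        assert s.mean == pytest.approx(1.0, abs=0.01)
        assert s.q50 == pytest.approx(1.0, abs=0.01)
        assert 1.0 - s.q10 == pytest.approx(s.q90 - 1.0, abs=0.01)

    def test_delta(self):
        dist = WeightedDistribution(
            "length", np.array([42.0]), np.array([1.0]), "mass", discrete=True
        )
        s = summarize(dist)
        assert s.q10 == s.q50 == s.q90 == s.mode == 42.0

    def test_afm_like_fixture_mean(self, afm_lengths):
        dist = ingest_length_table(afm_lengths, bins=64)
        mass = convert_weighting(dist, "mass")
        s = summarize(mass)
        # number-basis sample mean targets 395 nm; the mass-weighted mean
        # is pulled up by the length weighting
        s_num = summarize(dist)
        assert s_num.mean == pytest.approx(395.0, rel=0.02)
        assert s.mean > s_num.mean

    def test_modal_s_in_measured_band(self, material, solvent):
        """Mapped AFM-like length distributions with mean lengths in
        300-600 nm put the modal s inside the experimentally observed
        25-42 S band."""
        for mean_nm in (300.0, 450.0, 600.0):
            lengths = generate_afm_lengths(
                n=2000, mean_nm=mean_nm, min_nm=0.2 * mean_nm,
                max_nm=2.05 * mean_nm, seed=11,
            )
            dist = convert_weighting(ingest_length_table(lengths, bins=64), "mass")
            sdist = length_dist_to_s_dist(dist, 4.7, material, solvent)
            assert 25.0 <= sdist.mode() <= 42.0
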