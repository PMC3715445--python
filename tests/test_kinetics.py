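"""Dwell-time mixture, renewal convolutions, Gaussian theory, sampling."""

import numpy as np
import pytest
from scipy import stats

from tickertape import (
    PolymeraseKinetics,
    StartTimeModel,
    TimeGrid,
    dwell_time_pdf,
    gaussian_approximation,
    incorporation_mass_matrix,
    incorporation_time_distribution,
    sample_incorporation_times,
    template_length_for_duration,
)


class TestDwellModel:
    def test_pure_exponential_at_origin(self):
        kin = PolymeraseKinetics(20.0, 300.0, 0.0)
        assert dwell_time_pdf(kin, 0.0) == pytest.approx(1.0 / 20.0)

    def test_degenerate_mixture_collapses(self):
        kin = PolymeraseKinetics(1.0, 1.0, 0.5)
        assert dwell_time_pdf(kin, 2.0) == pytest.approx(np.exp(-2.0))

    @pytest.mark.parametrize(
        "kin",
        [
            PolymeraseKinetics(20.0, 300.0, 0.05),
            PolymeraseKinetics(5.0, 40.0, 0.3),
            PolymeraseKinetics(1.0, 100.0, 0.0),
            PolymeraseKinetics(10.0, 200.0, 0.1, dissoc_prob=0.001, tau_reassoc=5000.0),
        ],
    )
    def test_numeric_mean_matches_mixture_mean(self, kin):
        from scipy.integrate import quad

        hi = 200.0 * max(kin.tau_e, kin.tau_p, kin.tau_reassoc or 0.0)
        mean, _ = quad(
            lambda t: t * dwell_time_pdf(kin, t), 0.0, hi,
            points=[kin.tau_e, kin.tau_p], limit=200,
        )
        assert mean == pytest.approx(kin.mean_dwell, rel=1e-6)

    def test_density_normalizes(self):
        from scipy.integrate import quad

        kin = PolymeraseKinetics(20.0, 300.0, 0.05)
        total, _ = quad(lambda t: dwell_time_pdf(kin, t), 0.0, 60_000.0, points=[20.0, 300.0], limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_negative_time_rejected(self):
        kin = PolymeraseKinetics(20.0, 300.0, 0.05)
        with pytest.raises(ValueError):
            dwell_time_pdf(kin, -1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tau_e=-1.0, tau_p=300.0, pause_prob=0.05),
            dict(tau_e=20.0, tau_p=0.0, pause_prob=0.05),
            dict(tau_e=20.0, tau_p=300.0, pause_prob=1.5),
            dict(tau_e=20.0, tau_p=300.0, pause_prob=0.6, dissoc_prob=0.5),
            dict(tau_e=20.0, tau_p=300.0, pause_prob=0.05, dissoc_prob=0.01),
        ],
    )
    def test_invalid_kinetics_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PolymeraseKinetics(**kwargs)

    def test_dissociation_adds_third_component(self):
        kin = PolymeraseKinetics(20.0, 300.0, 0.05, dissoc_prob=0.01, tau_reassoc=2000.0)
        w, tau = kin.mixture()
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(0.94)
        assert kin.mean_dwell == pytest.approx(0.94 * 20 + 0.05 * 300 + 0.01 * 2000)


class TestIncorporationTimes:
    def test_first_nucleotide_is_discretized_dwell(self, phi29):
        grid = TimeGrid(4.0, 4000.0)
        d = incorporation_time_distribution(phi29, 1, grid)
        from tickertape.kinetics import dwell_pmf

        pmf, tail = dwell_pmf(phi29, grid)
        np.testing.assert_allclose(d.pmf, pmf, atol=1e-12)
        assert d.tail_mass == pytest.approx(tail, abs=1e-12)

    @pytest.mark.parametrize("i", [1, 3, 10, 50])
    def test_matches_erlang_when_no_pausing(self, i):
        kin = PolymeraseKinetics(20.0, 300.0, 0.0)
        grid = TimeGrid(4.0, 4000.0)
        d = incorporation_time_distribution(kin, i, grid, method="exact")
        erlang = np.diff(stats.gamma.cdf(grid.edges, a=i, scale=20.0))
        assert np.max(np.abs(d.pmf - erlang)) < 1e-6

    def test_renewal_mean_for_mixed_kinetics(self, phi29):
        # mean of the 50-fold convolution = 50 x mixture mean = 1700 ms
        grid = TimeGrid(4.0, 12_000.0)
        d = incorporation_time_distribution(phi29, 50, grid, method="exact")
        assert d.tail_mass < 1e-4
        assert d.mean == pytest.approx(50 * phi29.mean_dwell, rel=0.01)

    @pytest.mark.parametrize("i", [1, 7, 60, 300])
    def test_normalization_with_tail(self, phi29, i):
        d = incorporation_time_distribution(phi29, i, TimeGrid(4.0, 2000.0), method="exact")
        assert d.pmf.sum() + d.tail_mass == pytest.approx(1.0, abs=1e-9)
        assert np.all(d.pmf >= 0)

    def test_renewal_variance(self, phi29):
        grid = TimeGrid(4.0, 16_000.0)
        d = incorporation_time_distribution(phi29, 50, grid, method="exact")
        centers = grid.centers
        var = d.pmf @ centers**2 - (d.pmf @ centers) ** 2
        assert var == pytest.approx(50 * phi29.var_dwell, rel=0.02)

    def test_resolution_error(self, phi29):
        with pytest.raises(ValueError):
            incorporation_time_distribution(phi29, 5, TimeGrid(50.0, 1000.0))

    def test_index_domain_error(self, phi29):
        with pytest.raises(ValueError):
            incorporation_time_distribution(phi29, 0, TimeGrid(4.0, 1000.0))

    def test_start_delay_shifts_mean(self, phi29):
        grid = TimeGrid(4.0, 20_000.0)
        start = StartTimeModel(mean_delay=2000.0)
        d0 = incorporation_time_distribution(phi29, 50, grid, method="exact")
        d1 = incorporation_time_distribution(phi29, 50, grid, method="exact", start=start)
        assert d1.mean - d0.mean == pytest.approx(2000.0, rel=0.02)


class TestGaussianApproximation:
    def test_erlang_moments_when_no_pausing(self):
        kin = PolymeraseKinetics(20.0, 300.0, 0.0)
        ga = gaussian_approximation(kin, 9)
        assert ga.mu == pytest.approx(9 * 20.0)
        assert ga.sigma == pytest.approx(3 * 20.0)

    def test_sigma_sqrt_scaling(self, phi29):
        s1 = gaussian_approximation(phi29, 1).sigma
        s4 = gaussian_approximation(phi29, 4).sigma
        assert s4 / s1 == pytest.approx(2.0)

    def test_ks_distance_at_large_index(self, phi29):
        # frozen from the exact-convolution oracle: KS ~ 0.030 at i=400 for
        # these kinetics (dwell skewness ~9); Monte-Carlo confirmed
        grid = TimeGrid(4.0, 28_000.0)
        ex = incorporation_time_distribution(phi29, 400, grid, method="exact")
        ga = incorporation_time_distribution(phi29, 400, grid, method="gauss")
        ks = np.max(np.abs(np.cumsum(ex.pmf) - np.cumsum(ga.pmf)))
        assert ks < 0.035

    def test_ks_distance_decreases_along_index_ladder(self, phi29):
        ks = []
        for i in (10, 40, 160, 640):
            hi = 4.0 * int(np.ceil((i * 34.0 + 12 * np.sqrt(i) * 92.8) / 4.0))
            grid = TimeGrid(4.0, hi)
            ex = incorporation_time_distribution(phi29, i, grid, method="exact")
            ga = incorporation_time_distribution(phi29, i, grid, method="gauss")
            ks.append(np.max(np.abs(np.cumsum(ex.pmf) - np.cumsum(ga.pmf))))
        assert all(a > b for a, b in zip(ks, ks[1:]))


class TestMassMatrix:
    def test_rows_sum_to_one(self, phi29):
        edges = np.array([0.0, 500.0, 1500.0, 4000.0])
        for method in ("auto", "edgeworth", "gauss", "exact"):
            M, tail = incorporation_mass_matrix(
                phi29, np.array([1, 5, 80, 200, 2000]), edges, method=method
            )
            np.testing.assert_allclose(M.sum(axis=1) + tail, 1.0, atol=1e-8)
            assert np.all(M >= -1e-12)

    def test_edgeworth_matches_exact_on_coarse_bins(self, phi29):
        # signal bins far coarser than the dwell scale: approximation error
        # per bin must be negligible for the positions decoders care about
        edges = np.arange(0.0, 20_001.0, 5000.0)
        idx = np.array([120, 200, 350, 500])
        Me, te = incorporation_mass_matrix(phi29, idx, edges, method="exact")
        Ma, ta = incorporation_mass_matrix(phi29, idx, edges, method="edgeworth")
        assert np.max(np.abs(Me - Ma)) < 1e-2
        Mg, _ = incorporation_mass_matrix(phi29, idx, edges, method="gauss")
        # the skew correction must improve on the plain Gaussian
        assert np.max(np.abs(Me - Ma)) < np.max(np.abs(Me - Mg))

    def test_edgeworth_accuracy_at_calibration_scales(self, phi29):
        # 150 s signal segments, positions deep into the template: the
        # skew-corrected masses agree with the exact convolution to ~1e-5
        edges = np.arange(0.0, 600_001.0, 150_000.0)
        idx = np.array([1500, 4400, 8800])
        Me, _ = incorporation_mass_matrix(phi29, idx, edges, method="exact")
        Ma, _ = incorporation_mass_matrix(phi29, idx, edges, method="edgeworth")
        assert np.max(np.abs(Me - Ma)) < 5e-5

    def test_start_time_model_mass_concentration(self):
        # default gamma shape: >= 97.5% of start delays below twice the mean
        start = StartTimeModel(mean_delay=1000.0)
        frac = stats.gamma.cdf(2000.0, a=start.shape, scale=start.scale)
        assert frac >= 0.975


class TestSampling:
    def test_deterministic_under_seed(self, phi29):
        a = sample_incorporation_times(phi29, 100, 7)
        b = sample_incorporation_times(phi29, 100, 7)
        np.testing.assert_array_equal(a, b)

    def test_strictly_increasing(self, phi29, rng):
        t = sample_incorporation_times(phi29, 500, rng)
        assert np.all(np.diff(t) > 0)

    def test_law_of_large_numbers(self):
        kin = PolymeraseKinetics(10.0, 100.0, 0.0)
        rng = np.random.default_rng(0)
        finals = [sample_incorporation_times(kin, 1000, rng)[-1] for _ in range(2000)]
        assert np.mean(finals) == pytest.approx(10_000.0, rel=0.02)

    def test_start_delay_additivity(self):
        kin = PolymeraseKinetics(10.0, 100.0, 0.0)
        start = StartTimeModel(mean_delay=1000.0)
        rng = np.random.default_rng(0)
        firsts = [
            sample_incorporation_times(kin, 1, rng, start=start)[0] for _ in range(4000)
        ]
        assert np.mean(firsts) == pytest.approx(10.0 + 1000.0, rel=0.02)

    def test_sampled_histogram_matches_convolution(self):
        # chi-square goodness of fit of sampled 5th-incorporation times
        kin = PolymeraseKinetics(5.0, 50.0, 0.2)
        grid = TimeGrid(5.0, 600.0)
        d = incorporation_time_distribution(kin, 5, grid, method="exact")
        rng = np.random.default_rng(3)
        w, tau = kin.mixture()
        comp = rng.choice(len(w), size=(100_000, 5), p=w)
        samples = rng.exponential(tau[comp]).sum(axis=1)
        counts, _ = np.histogram(samples, bins=np.append(grid.edges, np.inf))
        expected = 100_000 * np.append(d.pmf, d.tail_mass)
        keep = expected > 5
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        p = stats.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01


def test_template_length_covers_duration(phi29):
    L = template_length_for_duration(phi29, 1_200_000.0)
    mu = L * phi29.mean_dwell
    sig = np.sqrt(L) * phi29.std_dwell
    assert mu >= 1_200_000.0 + 4 * sig
    # minimality: one template shorter must violate the coverage rule
    mu1 = (L - 1) * phi29.mean_dwell
    sig1 = np.sqrt(L - 1) * phi29.std_dwell
    assert mu1 < 1_200_000.0 + 4 * sig1
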