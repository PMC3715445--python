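"""Continuous and binary decoders plus the error metrics."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear
from scipy.special import xlog1py, xlogy

from tickertape import (
    ConcentrationTrace,
    LinearCMLF,
    MisincorporationTable,
    PolymeraseKinetics,
    TimeGrid,
    bit_accuracy,
    decode_binary,
    decode_continuous,
    estimation_error,
    incorporation_mass_matrix,
    misincorporation_profile,
    simulate_templates,
    template_length_for_duration,
)

from conftest import make_trace


def noiseless_table(kin, f, trace, N, L, **kw):
    prof = misincorporation_profile(kin, f, trace, L, **kw).probabilities
    x = np.round(N * prof).astype(np.int64)
    return MisincorporationTable(np.full(L, N), x)


class TestContinuousDecoder:
    def test_noiseless_constant_recovery(self, phi29, dpo4_link):
        grid = TimeGrid(150_000.0, 1_200_000.0)
        trace = ConcentrationTrace(grid, np.full(8, 0.6))
        L = template_length_for_duration(phi29, grid.t_max)
        tab = noiseless_table(phi29, dpo4_link, trace, 1_000_000, L)
        res = decode_continuous(tab, phi29, dpo4_link, 150_000.0, grid.t_max)
        np.testing.assert_allclose(res.values, 0.6, atol=1e-3)

    def test_zero_counts_zero_baseline(self, phi29):
        f = LinearCMLF(0.0, 0.03)
        L = 500
        tab = MisincorporationTable(np.full(L, 100), np.zeros(L, dtype=int))
        res = decode_continuous(tab, phi29, f, 2000.0, 16_000.0)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-9)

    def test_estimates_stay_in_box(self, phi29, dpo4_link, rng):
        trace = make_trace(rng.uniform(0, 1, 8), 1000.0)
        L = template_length_for_duration(phi29, trace.t_final)
        tab = simulate_templates(phi29, dpo4_link, trace, 50, L, rng)
        res = decode_continuous(tab, phi29, dpo4_link, 1000.0, trace.t_final)
        assert np.all(res.values >= 0.0) and np.all(res.values <= 1.0)

    def test_objective_not_worse_than_initialization(self, phi29, dpo4_link, rng):
        trace = make_trace(rng.uniform(0, 1, 6), 2000.0)
        L = template_length_for_duration(phi29, trace.t_final)
        tab = simulate_templates(phi29, dpo4_link, trace, 200, L, rng)
        res = decode_continuous(tab, phi29, dpo4_link, 2000.0, trace.t_final)
        # objective at the deterministic constant initialization
        c0 = np.clip((np.mean(tab.rates) - 0.005) / 0.025, 0, 1)
        M, tail = incorporation_mass_matrix(
            phi29, np.arange(1, L + 1), trace.grid.edges
        )
        Mc = M.copy()
        Mc[:, -1] += tail
        pred = 0.005 + 0.025 * (Mc @ np.full(6, c0))
        obj0 = np.sum((tab.n_misinc - tab.n_templates * pred) ** 2)
        assert res.objective <= obj0 + 1e-9

    def test_matches_box_constrained_least_squares(self, phi29, dpo4_link, rng):
        # independent solver for the identical quadratic program
        trace = make_trace(rng.uniform(0, 1, 5), 3000.0)
        L = template_length_for_duration(phi29, trace.t_final)
        tab = simulate_templates(phi29, dpo4_link, trace, 300, L, rng)
        res = decode_continuous(tab, phi29, dpo4_link, 3000.0, trace.t_final)
        M, tail = incorporation_mass_matrix(phi29, np.arange(1, L + 1), trace.grid.edges)
        Mc = M.copy()
        Mc[:, -1] += tail
        N = tab.n_templates.astype(float)
        A = (N * 0.025)[:, None] * Mc
        b = tab.n_misinc - N * 0.005
        ref = lsq_linear(A, b, bounds=(0.0, 1.0), tol=1e-12)
        np.testing.assert_allclose(res.values, ref.x, atol=3e-4)

    def test_consistency_with_growing_templates(self, phi29, dpo4_link):
        grid = TimeGrid(150_000.0, 600_000.0)
        true_vals = np.array([0.8, 0.2, 0.55, 0.35])
        trace = ConcentrationTrace(grid, true_vals)
        L = template_length_for_duration(phi29, grid.t_max)
        meds = []
        for N in (100, 1000, 10_000):
            rng = np.random.default_rng(99)
            errs = []
            for _ in range(5):
                tab = simulate_templates(phi29, dpo4_link, trace, N, L, rng)
                res = decode_continuous(tab, phi29, dpo4_link, 150_000.0, grid.t_max)
                errs.append(np.abs(res.values - true_vals))
            meds.append(np.median(errs))
        assert meds[0] > meds[1] > meds[2]

    def test_sparsity_penalty_pulls_toward_zero(self, phi29, dpo4_link, rng):
        trace = make_trace([0.4, 0.4, 0.4], 4000.0)
        L = template_length_for_duration(phi29, trace.t_final)
        tab = simulate_templates(phi29, dpo4_link, trace, 500, L, rng)
        free = decode_continuous(tab, phi29, dpo4_link, 4000.0, trace.t_final)
        reg = decode_continuous(
            tab, phi29, dpo4_link, 4000.0, trace.t_final, lambda_sparse=1e4
        )
        assert reg.values.sum() < free.values.sum()

    def test_smoothness_penalty_reduces_roughness(self, phi29, dpo4_link, rng):
        trace = make_trace(rng.uniform(0, 1, 8), 1500.0)
        L = template_length_for_duration(phi29, trace.t_final)
        tab = simulate_templates(phi29, dpo4_link, trace, 50, L, rng)
        free = decode_continuous(tab, phi29, dpo4_link, 1500.0, trace.t_final)
        reg = decode_continuous(
            tab, phi29, dpo4_link, 1500.0, trace.t_final, lambda_smooth=1e6
        )
        assert np.sum(np.diff(reg.values) ** 2) < np.sum(np.diff(free.values) ** 2)


def naive_binary_ml(table, kin, f, bin_ms, k, prefix_vals):
    """Independent re-implementation: loop over candidates, full table."""
    n_pre = len(prefix_vals)
    t_final = (n_pre + k) * bin_ms
    edges = bin_ms * np.arange(n_pre + k + 1)
    M, tail = incorporation_mass_matrix(kin, np.arange(1, table.L + 1), edges)
    best = None
    for c in range(2**k):
        bits = [(c >> (k - 1 - j)) & 1 for j in range(k)]
        vals = np.concatenate([prefix_vals, bits])
        E = f.e0 + f.m * (M @ vals + tail * vals[-1])
        E = np.clip(E, 1e-300, 1 - 1e-16)
        ll = float(
            np.sum(xlogy(table.n_misinc, E) + xlog1py(table.n_templates - table.n_misinc, -E))
        )
        if best is None or ll > best[0]:
            best = (ll, bits)
    return best


class TestBinaryDecoder:
    def test_single_bit_noiseless(self):
        kin = PolymeraseKinetics(1.0, 100.0, 0.0)
        f = LinearCMLF(0.005, 0.025)
        trace = make_trace([1.0], 100.0)
        L = template_length_for_duration(kin, 100.0)
        tab = noiseless_table(kin, f, trace, 10_000, L)
        res = decode_binary(tab, kin, f, 100.0, 1)
        assert res.values.tolist() == [1.0]

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_equals_independent_brute_force(self, k, rng):
        kin = PolymeraseKinetics(1.0, 100.0, 0.0)
        f = LinearCMLF(0.01, 0.05)
        n_pre = 7
        bin_ms = 100.0
        bits = rng.integers(0, 2, n_pre + k)
        trace = make_trace(bits.astype(float), bin_ms)
        L = template_length_for_duration(kin, trace.t_final)
        tab = simulate_templates(kin, f, trace, 300, L, rng)
        prefix = make_trace(bits[:n_pre].astype(float), bin_ms)
        res = decode_binary(tab, kin, f, bin_ms, k, known_prefix=prefix, prune_tol=0.0)
        ll_naive, bits_naive = naive_binary_ml(tab, kin, f, bin_ms, k, bits[:n_pre].astype(float))
        assert res.values.astype(int).tolist() == bits_naive
        assert res.objective == pytest.approx(ll_naive, abs=1e-6)

    def test_tie_breaks_to_lexicographically_smaller(self):
        # concentration-blind link: every candidate has identical likelihood
        kin = PolymeraseKinetics(1.0, 100.0, 0.0)
        f = LinearCMLF(0.02, 0.0)
        L = 50
        tab = MisincorporationTable(np.full(L, 100), np.full(L, 2))
        res = decode_binary(tab, kin, f, 100.0, 3, prune_tol=0.0)
        assert res.values.tolist() == [0.0, 0.0, 0.0]

    def test_bit_limit_enforced(self, fast_kin, dpo4_link):
        tab = MisincorporationTable(np.full(10, 10), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            decode_binary(tab, fast_kin, dpo4_link, 100.0, 11)

    def test_early_recording_high_accuracy(self):
        # 30 s trace at 100 ms bins, final 10 bits: far inside the feasible
        # region, so per-bit accuracy should exceed 99%
        from tickertape.experiments import terminal_window_accuracy

        kin = PolymeraseKinetics(1.0, 100.0, 0.0)
        f = LinearCMLF(0.005, 0.025)
        rng = np.random.default_rng(0)
        acc = terminal_window_accuracy(kin, f, 10_000, 100.0, 30_000.0, 200, rng)
        assert acc > 0.99


class TestErrorMetrics:
    def test_perfect_estimates(self):
        trace = make_trace([0.2, 0.8], 1000.0)
        summ = estimation_error(trace, [trace.values.copy() for _ in range(5)])
        assert summ.median_abs_error == 0.0

    def test_uniform_offset(self):
        trace = make_trace([0.2, 0.5, 0.3], 1000.0)
        ests = [trace.values + 0.1 for _ in range(4)]
        summ = estimation_error(trace, ests)
        assert summ.median_abs_error == pytest.approx(10.0)
        assert summ.ci95[0] <= summ.median_abs_error <= summ.ci95[1]

    def test_bootstrap_ci_shrinks_with_replicates(self, rng):
        trace = make_trace([0.5] * 4, 1000.0)
        widths = []
        for R in (8, 32, 128, 512):
            ests = [np.clip(0.5 + rng.normal(0, 0.1, 4), 0, 1) for _ in range(R)]
            summ = estimation_error(trace, ests, rng=rng)
            widths.append(summ.ci95[1] - summ.ci95[0])
        assert widths[0] > widths[-1]
        # rough 1/sqrt(R) scaling across the 64-fold ladder
        assert widths[-1] < widths[0] / 3.0

    def test_empty_input_rejected(self):
        trace = make_trace([0.5], 1000.0)
        with pytest.raises(ValueError):
            estimation_error(trace, [])


class TestBitAccuracy:
    def test_identical(self):
        assert bit_accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_complement(self):
        assert bit_accuracy([1, 0, 1], [0, 1, 0]) == 0.0

    def test_one_wrong_in_ten(self):
        t = np.zeros(10, dtype=int)
        d = t.copy()
        d[3] = 1
        assert bit_accuracy(t, d) == pytest.approx(0.9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bit_accuracy([1, 0], [1, 0, 1])
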