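"""Reproducible feasibility sweeps: recording-duration limits, minimum
polymerase speed, continuous-decoding error sweeps and stress tests.

The binary feasibility questions (how long can one record at a given
temporal resolution, and how fast must the polymerase be) are answered with
the terminal-window protocol: for each candidate duration a full random
binary trace is generated at the stated resolution, the final 10-bit window
is decoded by exhaustive binomial maximum likelihood with the earlier trace
known, and per-bit accuracy is pooled over replicate traces.  The terminal
window is the hardest part of the recording — the polymerase ensemble is
maximally de-phased there — so it is the binding constraint on duration.

A dedicated fast path exploits two structural facts: every template
position that can influence the window has a large index (so the Gaussian
incorporation-time approximation applies, vectorized over positions), and
positions whose window mass is below 1e-9 provably cannot change the argmax
given a known prefix, so they are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import ndtr
from scipy.optimize import minimize_scalar
from scipy.special import xlog1py, xlogy

from .decode import candidate_bits, decode_continuous, estimation_error
from .fisher import FisherResult, PulseSpec, fisher_information_full
from .kinetics import (
    PolymeraseKinetics,
    StartTimeModel,
    TimeGrid,
    template_length_for_duration,
)
from .link import ConcentrationTrace, LinearCMLF
from .simulate import simulate_templates

__all__ = [
    "SweepSpec",
    "SweepResult",
    "terminal_window_accuracy",
    "max_recording_duration",
    "min_required_speed",
    "error_sweep",
    "run_recorder_demo",
    "single_pulse_ml_experiment",
]

_Z_PRUNE = 6.2  # normal quantile with tail < 1e-9, used to bound relevant positions


# ---------------------------------------------------------------------------
# terminal-window binary decoding engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _WindowDesign:
    """Precomputed per-duration design shared by all replicate traces."""

    keep_idx: np.ndarray
    M_pre: np.ndarray  # masses over prefix bins inside the band
    W: np.ndarray  # masses over the k window bins, tail folded into the last
    b0: int  # first trace bin of the band
    n_bins: int
    k: int


def _window_design(
    kin: PolymeraseKinetics,
    resolution_ms: float,
    duration_ms: float,
    k_bits: int,
    start: StartTimeModel | None,
    prune_tol: float = 1e-9,
) -> _WindowDesign:
    mu_d, sd_d = kin.mean_dwell, kin.std_dwell
    n_bins = int(round(duration_ms / resolution_ms))
    window_ms = k_bits * resolution_ms
    t_win = duration_ms - window_ms

    L = template_length_for_duration(kin, duration_ms)
    sig_hi = np.sqrt(L) * sd_d
    # positions with mass >= prune_tol at/beyond the window start
    extra_mu = start.mean_delay if start is not None else 0.0
    i_min = max(1, int(np.floor((t_win - _Z_PRUNE * sig_hi - extra_mu) / mu_d)))
    idx = np.arange(i_min, L + 1, dtype=np.int64)

    mu = idx * mu_d
    var = idx * float(kin.var_dwell)
    if start is not None and start.mean_delay > 0:
        mu = mu + start.mean_delay
        var = var + start.var
    sig = np.sqrt(var)

    keep = 1.0 - ndtr((t_win - mu) / sig) >= prune_tol
    idx, mu, sig = idx[keep], mu[keep], sig[keep]

    # band of trace bins holding (to < 1e-9) all mass of every kept position
    band_lo = mu[0] - _Z_PRUNE * sig[0]
    b0 = min(max(0, int(np.floor(band_lo / resolution_ms))), n_bins - k_bits)
    edges = resolution_ms * np.arange(b0, n_bins + 1)

    cdf = ndtr((edges[None, :] - mu[:, None]) / sig[:, None])
    M = np.diff(cdf, axis=1)
    M[:, 0] += cdf[:, 0]
    tail = 1.0 - cdf[:, -1]
    W = M[:, -k_bits:].copy()
    W[:, -1] += tail  # "extend-last-value" tail policy
    return _WindowDesign(
        keep_idx=idx, M_pre=M[:, :-k_bits], W=W, b0=b0, n_bins=n_bins, k=k_bits
    )


def terminal_window_accuracy(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    N: int,
    resolution_ms: float,
    duration_ms: float,
    n_replicates: int,
    rng: np.random.Generator,
    k_bits: int = 10,
    start: StartTimeModel | None = None,
) -> float:
    """Pooled per-bit accuracy of terminal-window ML decoding.

    Each replicate draws a fresh random binary trace over the whole
    recording, simulates binomial counts for every window-relevant position
    (profile mode), and decodes the final ``k_bits`` bins exhaustively with
    the earlier trace known.  Log-likelihoods are accumulated in float32
    with probabilities clipped to [1e-9, 1 - 1e-9]; impossible candidates
    are penalized far beyond any achievable likelihood gap.
    """
    des = _window_design(kin, resolution_ms, duration_ms, k_bits, start)
    B = candidate_bits(k_bits)
    B32t = B.T.astype(np.float32)
    W32 = des.W.astype(np.float32)
    m32 = np.float32(f.m)
    dE = W32 @ B32t  # candidate-dependent overlap term, shared by replicates
    n_correct = 0
    for _ in range(n_replicates):
        bits = rng.integers(0, 2, size=des.n_bins)
        pre = bits[des.b0 : des.n_bins - k_bits].astype(float)
        win = bits[des.n_bins - k_bits :]
        base = f.e0 + f.m * (des.M_pre @ pre)
        e_true = base + f.m * (des.W @ win)
        x = rng.binomial(N, np.clip(e_true, 0.0, 1.0))

        E = base.astype(np.float32)[:, None] + m32 * dE
        # clip to a float32-safe open interval; the boundary penalty
        # (~20.7 nats per contradicting count) dwarfs any real likelihood gap
        np.clip(E, np.float32(1e-9), np.float32(1.0 - 1e-6), out=E)
        x32 = x.astype(np.float32)
        n_minus_x = np.float32(N) - x32
        # center each position's terms at the saturated model so the summands
        # are O(1): raw log-likelihoods are ~1e7 and float32 accumulation
        # error would otherwise rival real candidate gaps (a few nats)
        ehat = np.clip(x32 / np.float32(N), np.float32(1e-6), np.float32(1 - 1e-6))
        logE = np.log(E)
        logE -= np.log(ehat)[:, None]
        log1mE = np.log1p(-E)
        log1mE -= np.log1p(-ehat)[:, None]
        ll = x32 @ logE + n_minus_x @ log1mE
        best = int(np.argmax(ll))
        n_correct += int(np.sum(B[best] == win))
    return n_correct / (n_replicates * k_bits)


def _largest_feasible(
    grid: np.ndarray,
    acc_fn,
    threshold: float,
    n_replicates: int,
    coarse_replicates: int,
    rng: np.random.Generator,
) -> float:
    """Largest grid value whose accuracy >= threshold, assuming accuracy is
    monotone non-increasing along the grid.  A coarse bisection locates the
    boundary; the bracketing points are then confirmed at full replicates.
    """
    lo, hi = 0, len(grid) - 1
    if acc_fn(grid[0], coarse_replicates, rng) < threshold:
        # even the smallest grid point may fail; confirm at full replicates
        if acc_fn(grid[0], n_replicates, rng) < threshold:
            return 0.0
        hi = 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if acc_fn(grid[mid], coarse_replicates, rng) >= threshold:
            lo = mid
        else:
            hi = mid - 1
    # refine with full replicates, walking if the coarse scan was off by a step
    best = lo
    while best >= 0 and acc_fn(grid[best], n_replicates, rng) < threshold:
        best -= 1
    if best < 0:
        return 0.0
    while best + 1 < len(grid) and acc_fn(grid[best + 1], n_replicates, rng) >= threshold:
        best += 1
    return float(grid[best])


def max_recording_duration(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    N: int,
    resolution_ms: float = 100.0,
    threshold: float = 0.95,
    duration_grid_s: np.ndarray | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    k_bits: int = 10,
    coarse_replicates: int = 40,
    start: StartTimeModel | None = None,
) -> float:
    """Maximum recording duration (s) sustaining threshold per-bit accuracy.

    The search grid defaults to 25 s steps up to 2000 s.  Returns 0 if no
    grid duration is feasible (e.g. ``m = 0``).
    """
    if duration_grid_s is None:
        duration_grid_s = np.arange(25.0, 2025.0, 25.0)
    grid = np.asarray(duration_grid_s, float)
    if f.m == 0:
        return 0.0
    rng = np.random.default_rng(seed)

    def acc(dur_s, n_rep, r):
        return terminal_window_accuracy(
            kin, f, N, resolution_ms, dur_s * 1000.0, n_rep, r, k_bits=k_bits, start=start
        )

    return _largest_feasible(grid, acc, threshold, n_replicates, coarse_replicates, rng)


def min_required_speed(
    f: LinearCMLF,
    N: int,
    resolution_ms: float,
    record_s: float,
    threshold: float = 0.95,
    speed_grid: np.ndarray | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    k_bits: int = 10,
    coarse_replicates: int = 40,
    pause_prob: float = 0.0,
    tau_p: float = 100.0,
) -> float:
    """Smallest polymerase speed (nt/s) sustaining threshold accuracy over a
    ``record_s``-second recording; +inf when no grid speed is feasible.

    Speed maps to the elongation time as ``tau_e = 1000 / speed`` ms.
    Accuracy is monotone non-decreasing in speed, so the reversed grid can
    reuse the duration-search bisection.
    """
    if speed_grid is None:
        speed_grid = np.arange(500.0, 8250.0, 250.0)
    grid = np.asarray(speed_grid, float)
    rng = np.random.default_rng(seed)

    def acc(speed, n_rep, r):
        kin = PolymeraseKinetics(tau_e=1000.0 / speed, tau_p=tau_p, pause_prob=pause_prob)
        return terminal_window_accuracy(
            kin, f, N, resolution_ms, record_s * 1000.0, n_rep, r, k_bits=k_bits
        )

    if threshold <= 0:
        return float(grid[0])
    # descending speeds give monotone non-increasing accuracy
    best = _largest_feasible(
        grid[::-1], acc, threshold, n_replicates, coarse_replicates, rng
    )
    return best if best > 0 else np.inf


# ---------------------------------------------------------------------------
# continuous-decoding error sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep of the multi-condition continuous experiment.

    ``param`` selects what the grid varies: "N", "cmlf" (grid of (e0, m)
    pairs), "pausing" (grid of (P, tau_p) at fixed tau_e), "n_conditions",
    "start_mean_ms" (gamma start-time spread), "processivity" (mean
    nucleotides before dissociation; grid pairs (processivity,
    tau_reassoc_ms)), or "fluctuate" (grid of booleans: per-ms concentration
    jitter of +/- 0.2 around per-condition baselines in [0.2, 0.8], scored
    against the condition mean).
    """

    param: str
    grid: tuple
    kin: PolymeraseKinetics
    f: LinearCMLF
    N: int = 1000
    n_conditions: int = 8
    total_s: float = 1200.0
    n_replicates: int = 20
    seed: int = 0
    accuracy_threshold: float = 0.95
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        if not 0 < self.accuracy_threshold < 1:
            raise ValueError("accuracy_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    grid: tuple
    median_error: np.ndarray
    ci95: list[tuple[float, float]]
    provenance: dict[str, Any]


def _one_sweep_point(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    N: int,
    n_conditions: int,
    total_s: float,
    n_replicates: int,
    rng: np.random.Generator,
    start: StartTimeModel | None = None,
    fluctuate: bool = False,
) -> tuple[float, tuple[float, float]]:
    dt = total_s * 1000.0 / n_conditions
    grid = TimeGrid(dt, total_s * 1000.0)
    L = template_length_for_duration(kin, grid.t_max)
    ests, truths = [], []
    for _ in range(n_replicates):
        if fluctuate:
            base = rng.uniform(0.2, 0.8, size=n_conditions)
            # per-ms jitter around each condition baseline, aggregated to 1 s
            # bins for the forward model (E_i is linear in the trace, so
            # within-bin averaging is near-exact at these time scales); the
            # decoder is scored against the condition means
            fine = TimeGrid(1000.0, grid.t_max)
            per_s = int(dt // 1000)
            jitter = rng.uniform(-0.2, 0.2, size=(fine.n_bins, 1000)).mean(axis=1)
            vals = np.clip(np.repeat(base, per_s) + jitter, 0.0, 1.0)
            sim_trace = ConcentrationTrace(fine, vals)
            true_vals = base
        else:
            true_vals = rng.uniform(0.0, 1.0, size=n_conditions)
            sim_trace = ConcentrationTrace(grid, true_vals)
        tab = simulate_templates(kin, f, sim_trace, N, L, rng, mode="profile", start=start)
        res = decode_continuous(tab, kin, f, dt, grid.t_max, start=start)
        ests.append(res.values)
        truths.append(true_vals)
    errs = 100.0 * np.abs(np.stack(ests) - np.stack(truths))
    med = float(np.median(errs))
    boots = np.empty(1000)
    R = errs.shape[0]
    for b in range(1000):
        take = rng.integers(0, R, size=R)
        boots[b] = np.median(errs[take])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return med, (float(lo), float(hi))


def error_sweep(spec: SweepSpec) -> SweepResult:
    """Median continuous-decoding error across one parameter grid."""
    rng = np.random.default_rng(spec.seed)
    meds, cis = [], []
    for g in spec.grid:
        kin, f, N = spec.kin, spec.f, spec.N
        ncond, start, fluct = spec.n_conditions, None, False
        if spec.param == "N":
            N = int(g)
        elif spec.param == "cmlf":
            f = LinearCMLF(*g)
        elif spec.param == "pausing":
            P, tp = g
            kin = PolymeraseKinetics(tau_e=kin.tau_e, tau_p=tp, pause_prob=P)
        elif spec.param == "n_conditions":
            ncond = int(g)
        elif spec.param == "start_mean_ms":
            start = StartTimeModel(mean_delay=float(g))
        elif spec.param == "processivity":
            proc, tre = g
            kin = PolymeraseKinetics(
                tau_e=kin.tau_e,
                tau_p=kin.tau_p,
                pause_prob=kin.pause_prob,
                dissoc_prob=1.0 / proc,
                tau_reassoc=tre,
            )
        elif spec.param == "fluctuate":
            fluct = bool(g)
        else:
            raise ValueError(f"unknown sweep parameter {spec.param!r}")
        med, ci = _one_sweep_point(
            kin, f, N, ncond, spec.total_s, spec.n_replicates, rng, start=start, fluctuate=fluct
        )
        meds.append(med)
        cis.append(ci)
    prov = {"seed": spec.seed, "param": spec.param}
    return SweepResult(
        spec=spec, grid=spec.grid, median_error=np.array(meds), ci95=cis, provenance=prov
    )


# ---------------------------------------------------------------------------
# demos and diagnostics
# ---------------------------------------------------------------------------


def run_recorder_demo(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    word: str = "RECORDER",
    seconds_per_letter: float = 150.0,
    N_values: tuple[int, ...] = (1, 10, 100, 1000),
    n_replicates: int = 10,
    seed: int = 0,
) -> dict[int, dict]:
    """Encode a word as a concentration staircase, record and decode it.

    Returns per-N median error summaries plus the decoded word from the
    first replicate at each N.
    """
    from .simulate import decode_word, encode_word

    trace = encode_word(word, seconds_per_letter)
    L = template_length_for_duration(kin, trace.t_final)
    rng = np.random.default_rng(seed)
    out = {}
    for N in N_values:
        ests, words = [], []
        for _ in range(n_replicates):
            tab = simulate_templates(kin, f, trace, N, L, rng, mode="profile")
            res = decode_continuous(tab, kin, f, trace.grid.dt, trace.t_final)
            ests.append(res)
            words.append(decode_word(res.trace_estimate))
        summ = estimation_error(trace, ests, rng=rng)
        out[N] = {
            "median_error_pct": summ.median_abs_error,
            "ci95": summ.ci95,
            "decoded_words": words,
        }
    return out


def single_pulse_ml_experiment(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    pulse: PulseSpec,
    N: int,
    L: int,
    n_replicates: int = 500,
    seed: int = 0,
) -> dict[str, float | np.ndarray]:
    """Scalar ML estimation of a single-pulse peak concentration vs the CRB.

    Each replicate simulates Bernoulli counts at the true pulse
    concentration and maximizes the exact binomial likelihood over the peak
    concentration (other pulse properties known).  The estimator is left
    unconstrained within the range keeping every E_i in (0, 1), so its
    variance is comparable to the Cramér–Rao bound for unbiased estimators.
    """
    fr: FisherResult = fisher_information_full(kin, f, pulse, N, L)
    a = fr.alphas
    rng = np.random.default_rng(seed)
    amax = float(a.max())
    c_lo = -f.e0 / (f.m * amax) * 0.99 if f.e0 > 0 else 0.0
    c_hi = (1.0 - f.e0) / (f.m * amax) * 0.99
    c_lo, c_hi = max(c_lo, -1.0), min(c_hi, 2.0)

    e_true = f.e0 + f.m * pulse.conc * a
    keep = a > 1e-12  # uninformative positions only add likelihood constants
    ak, ek = a[keep], e_true[keep]

    def neg_ll(c, x):
        E = np.clip(f.e0 + f.m * c * ak, 1e-300, 1 - 1e-15)
        return -float(np.sum(xlogy(x, E) + xlog1py(N - x, -E)))

    est = np.empty(n_replicates)
    for r in range(n_replicates):
        x = rng.binomial(N, ek)
        res = minimize_scalar(neg_ll, args=(x,), bounds=(c_lo, c_hi), method="bounded")
        est[r] = res.x
    var = float(np.var(est, ddof=1))
    return {
        "estimates": est,
        "variance": var,
        "crb": fr.crb,
        "ratio": var / fr.crb,
        "info": fr.info,
    }
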