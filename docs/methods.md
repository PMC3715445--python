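# Methods

`tickertape` models a DNA-polymerase "molecular ticker tape": an ensemble
of engineered polymerases copies identical templates while a time-varying
scaled ion concentration `C(t) ∈ [0, 1]` modulates their per-base
misincorporation probability.  Sequencing the copies and counting
substitutions per template position yields a noisy, time-blurred image of
the signal; this package provides the forward model, the decoders that
invert it, the Fisher-information theory bounding what any decoder can do,
and the calibration machinery for unknown polymerase kinetics.

## Forward model

**Dwell times.**  The time between successive nucleotide additions is an
exponential mixture: with probability `1 − P` the polymerase proceeds along
the elongation path (mean `tau_e`), with probability `P` it takes a pausing
path (mean `tau_p`).  Dissociation is an optional third component (weight
`dissoc_prob = 1/processivity`, mean `tau_reassoc`).  All times are in
milliseconds.  This two/three-exponential mixture is the only dwell model;
mechanistic multi-substep catalytic cycles are out of scope.

**Incorporation times.**  The time of the i-th addition, `T_i`, is the
i-fold convolution of the dwell distribution (polymerases start at the
first nucleotide at t = 0, unless a gamma-distributed start delay is
modelled).  Numerically, `T_i` bin masses on a uniform grid are obtained by
inverting the mixture's characteristic function `phi(w)^i` (times the gamma
start-time factor) with a bin-integrating spectral window.  This is exact
up to (a) wrap-around past the padded support (< 1e-12 by construction)
and (b) Nyquist truncation, which decays like `(pi tau_min / dt_int)^-i`;
for small `i` the internal grid is refined until the bound is below 1e-9.
Iterated lattice self-convolution was rejected: its half-bin placement bias
grows linearly in `i` and visibly distorts the pmf (≈6e-3 per bin by
i = 10 at `dt = tau_e/5`).

**Large-index approximations.**  By the renewal CLT,
`T_i ≈ Normal(mu_i = i·E[dwell], sigma_i² = i·Var[dwell])`.  The package
exposes three accuracy tiers for per-position bin masses:

* `exact` — characteristic-function inversion (above);
* `gauss` — plain Gaussian CDF differences;
* `edgeworth` — Gaussian plus the one-term Edgeworth skewness correction
  `F(z) ≈ Φ(z) − φ(z)(z² − 1)·γ_i/6` with `γ_i = mu3_dwell/(sigma_dwell³ √i)`.

The default (`auto`) uses `exact` below index 100 and `edgeworth` above.
The skew term matters twice: it reduces the bin-mass error at calibration
scales from ~9e-3 (plain Gaussian) to ~1e-5, and it carries the
third-moment information without which the three kinetic parameters are
identified only up to a mean/variance-matching ridge (see Calibration).
For the full distribution object, the documented Gaussian switch applies a
one-time Kolmogorov–Smirnov gate (tolerance 0.02 at the switch index); for
strongly skewed kinetics such as the phi29-like default the gate fails
(true KS ≈ 0.03 at i = 400, verified against Monte Carlo) and exact
convolution is used instead.  Mass below t = 0 (an artifact of the
Gaussian) is folded into the first bin; mass beyond the last edge is
tracked explicitly as `tail_mass`, never dropped.

**Link and marginalization.**  The concentration-to-misincorporation link
function is linear: `f(C) = e0 + m·C`, with `e_h = e0 + m` the rate at
high concentration.  No defaults are supplied for `e0`/`m` — published
values for the figures this package emulates are not recoverable, so every
configuration must state them.  Because the addition time of nucleotide i
is random, its misincorporation probability marginalizes the link over
`T_i`:  `E_i = Σ_t f(C(t)) T_i(t) + tail_mass · f(C_tail)`.  Traces are
piecewise constant; the marginalization is a mass-matrix product.  The
tail concentration defaults to the last trace value ("extend"), avoiding
artificial error cliffs for positions replicated after the recording ends;
a "zero" policy is selectable.

## Simulator

`simulate_templates` produces the per-position count table
(`n_templates`, `n_misinc`) that an aligner would emit from real reads.
Profile mode draws `x_i ~ Binomial(N, E_i)` from the analytic profile and
is used for all sweeps; event mode samples every polymerase trajectory and
flips a Bernoulli coin at each sampled (sub-bin) incorporation time.  The
two modes have identical marginals (positions are conditionally
independent given the trace), which is verified distributionally in the
tests.  Only substitutions are modelled; indels and sequence-context
effects are out of scope.  The word demo maps letters to the 26-level
concentration ladder (A = 0/25 … Z = 25/25).

## Precision theory

For a single square pulse (start `t0`, duration `Δ`, peak `C`), position i
is replicated during the pulse with probability `alpha_i` (mass of `T_i`
in the pulse window), so each template/position pair is a Bernoulli trial
with `E_i(C) = e0 + m·C·alpha_i`.  The Fisher information about `C` is

    I(C) = N · Σ_i (m·alpha_i)² / (E_i (1 − E_i)),

additive over positions and templates; `1/I` is the Cramér–Rao bound.  The
small-error form drops the `(1 − E_i)` factor.  Both are verified against
an exhaustive expected-squared-score enumeration at tiny sizes.  The
multi-pulse information matrix has no simple closed form and is not
implemented; simulation with the decoders is the multi-pulse pathway.

The CRB-attainment experiment estimates the peak concentration of a late,
short pulse (15 s ending at t = 1200 s under phi29-like kinetics) by
scalar maximum likelihood over 500 simulated replicates.  The late
placement maximizes ensemble de-phasing, the regime where attainment is
non-trivial.  Because a 500-replicate sample variance has ~6% chi-square
noise while a well-behaved MLE here is essentially efficient, the check is
one-sided-aware: variance ≤ 1.5× CRB, and ≥ CRB minus a 3-sigma sampling
allowance.  A literal `variance ≥ CRB` assertion would fail half the time
for a perfectly efficient estimator, regardless of implementation quality.

## Decoders

**Continuous.**  The estimate minimizes
`Σ_i (x_i − N·E_i(C))² + λ_sparse Σ_b C_b + λ_smooth Σ_b (C_{b+1} − C_b)²`
subject to `0 ≤ C_b ≤ 1`, by projected gradient descent with a
backtracking quadratic-model line search (the cost is convex; the gradient
uses `dE_i/dC_b = m ×` bin mass of `T_i`).  Termination: relative
objective change < 1e-9 or projected-gradient norm < 1e-8; the best
iterate is returned flagged if the budget is exhausted.  Initialization is
the deterministic constant trace `clip((mean(x/N) − e0)/m, 0, 1)`,
unbiased under a constant signal.  Both penalties default to 0.  The
whole program is a box-constrained least-squares problem; tests cross-check
the minimizer against an independent bounded-least-squares solver.

**Binary.**  For `k ≤ 10` unknown bits the exact maximizer of the binomial
log-likelihood is found by enumerating all `2^k` candidates (the binomial
coefficient is candidate-independent and omitted); ties break toward the
lexicographically smaller bit string.  The earlier part of the trace can
be supplied as a known prefix.  Positions whose window mass (including
tail under "extend") is below 1e-9 cannot change the argmax and are
pruned.

**Terminal-window protocol.**  Feasibility questions (maximum recording
duration, minimum speed) are scored on the final 10-bit window of
full-length random binary traces with the earlier trace known: the
terminal window is where the ensemble is maximally de-phased, so it is the
binding constraint.  The dedicated engine vectorizes the Gaussian overlap
matrices (every relevant position has a large index) and accumulates
log-likelihoods in float32 after centering each position's terms at the
saturated model — raw log-likelihoods are ~1e7 nats and uncentered float32
accumulation error would rival real candidate gaps; centered, the float32
path reproduces the float64 decoder bit-for-bit at ~5× the speed.
Probabilities are clipped to a float32-safe open interval; the boundary
penalty (~21 nats per contradicting count) dwarfs any genuine likelihood
gap.

Duration and speed searches bisect their grids (accuracy is monotone in
both) with a coarse 40-replicate scan, then confirm the boundary at the
full 200 replicates, walking if the coarse scan was off by a step.

## Calibration

With the trace known and the link assumed known, the binomial
log-likelihood of the counts is maximized over `(tau_e, tau_p, P)` by
Nelder–Mead.  Three non-obvious choices:

* **Search space.**  The default parametrization is the log raw dwell
  moments `(m1, m2, m3)`, inverted to kinetics by Prony's method (the
  component means are roots of the quadratic built from the Hankel system
  of `S_r = m_r/r!`).  The likelihood is steep in `(m1, m2)` and nearly
  flat in `m3`, so this space is close to axis-separable; the direct
  `(log tau_e, log tau_p, logit P)` space is available but needs thousands
  of evaluations where moments need hundreds.
* **Time-scale scan.**  A wrong mean dwell mis-aligns template positions
  with signal segments, producing comb-like local optima.  A deterministic
  25-point scan along a pure time rescaling of the dwell distribution
  locates the aligned basin before Nelder–Mead starts; a restart from the
  best vertex with a fresh simplex guards against simplex collapse.
* **Likelihood evaluation.**  Per-position expected rates use the
  Edgeworth mass matrix (fully vectorized; exact-vs-Edgeworth bin-mass
  error < 2e-5 at 150 s segments).  A plain Gaussian must not be used
  here: it collapses the likelihood onto the dwell mean/variance, leaving
  the pause split unidentified.

Identifiability is intrinsically anisotropic: the dwell mean and variance
are pinned tightly by segment alignment, while the skewness direction —
which separates `(tau_e, tau_p, P)` individually — enters only through
third-moment corrections of order `gamma_1/√i` at segment boundaries.  On
noiseless data the expected log-likelihood drop for ±60% moment-matched
pause-parameter changes is under one nat at N = 1000 templates, so
individual-parameter errors in the tens of percent at N = 1000 are a
property of the experiment, not the optimizer; they fall to a few percent
by N = 10000.  Calibration experiments therefore use a stronger,
pol-Iota-like link (`e0 = 0.005`, `m = 0.095`) and are asserted as trends
(monotone in N, sharp drop from 10 to 100 templates, calibrated-decoding
error within 2 percentage points of known-parameter decoding).  A constant
calibration trace is rejected outright: it makes `E_i` position-
independent and the kinetics unidentifiable.  The shipped calibration
signal is 1,0,0,1,0,0,0,1 at 150 s per segment; a utility ranks candidate
traces by simulated recovery error.

## Synthetic study conditions

The feasibility sweeps fix the conditions used throughout: pause-free
1000 nt/s kinetics (`tau_e = 1` ms) and N = 10000 templates for binary
decoding at 100 ms resolution; 10 ms bins, a perfect link (`e0 = 0`,
`e_h = 100%`) and a 250 nt/s speed grid from 500 to 8000 nt/s for the
minimum-speed search; phi29-like kinetics (`tau_e = 20` ms,
`tau_p = 300` ms, `P = 0.05`) with a Dpo4-like link (`e0 = 0.005`,
`m = 0.025`) for continuous multi-condition demos, eight 150 s conditions
over 20 minutes.  Published parameter values for several figures are not
recoverable from the available text, so those experiments are asserted as
qualitative trends at these stated conditions.  Template length is always
the smallest L with `mu_L ≥ T + 4 sigma_L`.

What the simulator does not emulate: alignment and sequencing artifacts
(reads are assumed perfectly localized and error-free apart from
polymerase misincorporation), indels, sequence-context- or
mismatch-dependent rates, concentration-dependent elongation kinetics, and
nonlinear links.  Passing tests therefore demonstrate the statistical
machinery under the stated generative model, not robustness to those
real-data effects.

## Numerical notes and limitations

* Bin conventions: half-open `[k·dt, (k+1)·dt)`, 1-based template
  positions, traces piecewise constant on their own grid.
* Every distribution satisfies `sum(pmf) + tail_mass = 1` within 1e-9;
  tiny negative masses from floating-point cancellation are clamped to 0.
* The duration/speed accuracy estimates carry ~0.5% binomial noise at 200
  replicates; near-threshold boundaries can move by one 25 s grid step
  between seeds.  Accuracy-vs-duration curves are very flat near threshold
  for low-baseline links, so reported maxima are sensitive to the
  replicate budget there.
* Exhaustive binary search is limited to 10 bits by design; longer windows
  need combinatorial optimization outside this package's scope.
* Joint estimation of kinetics and an unknown signal (EM-style) is not
  implemented; calibration requires a known trace.
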