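# tickertape

Statistical machinery for DNA-polymerase **molecular ticker tapes** —
recording time-varying cellular signals (for example intracellular calcium)
into DNA as patterns of nucleotide misincorporations.

An engineered DNA polymerase (DNAP) copies many identical template strands
while the local ion concentration modulates its per-base misincorporation
probability.  Sequencing the copies and counting substitutions at each
template position yields a time-blurred image of the signal: the polymerase
has no clock, so the time of the i-th nucleotide addition is a random
variable whose spread grows with i.  This package implements the forward
model and the statistics needed to design and decode such experiments:

* **Kinetics** — dwell times as an exponential mixture over elongation
  (mean `tau_e`), pausing (mean `tau_p`, probability `P`) and optional
  dissociation paths; incorporation-time distributions `T_i` as i-fold
  convolutions (exact characteristic-function inversion, Gaussian and
  skew-corrected large-i approximations); gamma-distributed start delays.
* **Forward model** — the linear concentration-to-misincorporation link
  `f(C) = e0 + m·C` marginalized over `T_i`:
  `E_i = Σ_t f(C(t)) T_i(t)`.
* **Simulator** — per-position misincorporation count tables across N
  templates, as an aligner would produce from real reads (binomial profile
  mode and full event mode).
* **Precision theory** — single-pulse Fisher information
  `I(C) = N Σ_i (m·alpha_i)²/(E_i(1−E_i))` and the Cramér–Rao bound.
* **Decoders** — box-constrained least squares for continuous traces;
  exact maximum likelihood by exhaustive search over ≤ 10 bits for binary
  traces, with known-prefix support.
* **Calibration** — Nelder–Mead maximum likelihood for unknown
  `(tau_e, tau_p, P)` from counts recorded under a known signal.
* **Experiments** — reproducible sweeps: maximum recording duration vs
  link function, minimum required polymerase speed, error vs templates /
  link / pausing / start-time spread / dissociation.

## Worked example

Record the word RECORDER as a staircase of concentrations (A = 0/25 …
Z = 25/25, 150 s per letter), simulate sequencing counts, and decode:

```python
from tickertape import LinearCMLF, PolymeraseKinetics
from tickertape.experiments import run_recorder_demo

kin = PolymeraseKinetics(tau_e=20.0, tau_p=300.0, pause_prob=0.05)
link = LinearCMLF(e0=0.005, m=0.095)
out = run_recorder_demo(kin, link, word="RECORDER",
                        N_values=(1, 10, 100, 1000), n_replicates=5, seed=0)
```

which prints (per template count: median absolute error as % of the
concentration scale, and the decoded word):

```
N=    1  median error  1.46% (95% CI 1.26-2.08)  decoded: QECNQCER
N=   10  median error  0.81% (95% CI 0.54-1.00)  decoded: RECORDFQ
N=  100  median error  0.18% (95% CI 0.06-0.30)  decoded: RECORDER
N= 1000  median error  0.07% (95% CI 0.05-0.09)  decoded: RECORDER
```

One letter is 4% of the scale, so once the median error falls below ~2%
the word round-trips exactly; with a single template the record is still
legible but noisy.

Binary feasibility, from `examples/04_binary_recording_limit.py` — a
pause-free 1000 nt/s polymerase recording a random binary signal at 100 ms
resolution with a 3%-at-high-concentration link and 10000 templates:

```
duration  100 s: per-bit accuracy 1.000
duration  200 s: per-bit accuracy 0.993
duration  300 s: per-bit accuracy 0.943
duration  400 s: per-bit accuracy 0.883
longest duration with >= 95% accuracy (25 s grid): 250 s
```

Accuracy decays with duration because the incorporation-time spread grows
as `sqrt(position)`; the final seconds of a long recording are too
de-phased to resolve 100 ms bins.

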