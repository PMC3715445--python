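"""Synthetic sequencing outcomes under the forward model.

``simulate_templates`` produces the per-position misincorporation count
table that a real experiment would obtain by aligning reads to the known
template and counting substitutions.  Two modes are available:

* ``"profile"`` (default) — draw ``x_i ~ Binomial(N, E_i)`` from the analytic
  misincorporation profile; fast, used for all sweeps.
* ``"event"`` — simulate every template trajectory: sample incorporation
  times, then flip a Bernoulli coin with probability ``f(C(t_i))`` at each
  sampled (sub-bin) time.  Exists to validate the marginalization and for
  start-time / dissociation stress tests.

Both modes have identical marginal distributions of ``x_i`` because
templates are copied independently and positions are independent given the
trace.  Only substitution-type misincorporations are modelled; insertions
and deletions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import PolymeraseKinetics, StartTimeModel, TimeGrid, sample_incorporation_times
from .link import ConcentrationTrace, LinearCMLF, cmlf_eval, misincorporation_profile

__all__ = ["MisincorporationTable", "simulate_templates", "encode_word", "decode_word"]

_N_LETTERS = 26


@dataclass(frozen=True)
class MisincorporationTable:
    """Per-position replicate and misincorporation counts for positions 1..L."""

    n_templates: np.ndarray = field(repr=False)
    n_misinc: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = np.asarray(self.n_templates, dtype=np.int64)
        x = np.asarray(self.n_misinc, dtype=np.int64)
        object.__setattr__(self, "n_templates", n)
        object.__setattr__(self, "n_misinc", x)
        if n.shape != x.shape or n.ndim != 1:
            raise ValueError("n_templates and n_misinc must be 1-d arrays of equal length")
        if np.any(x < 0) or np.any(x > n):
            raise ValueError("counts must satisfy 0 <= n_misinc <= n_templates")

    @property
    def L(self) -> int:
        return self.n_templates.size

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.L + 1)

    @property
    def rates(self) -> np.ndarray:
        """Observed misincorporation frequency per position."""
        return self.n_misinc / np.maximum(self.n_templates, 1)


def simulate_templates(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    trace: ConcentrationTrace,
    N: int,
    L: int,
    rng: np.random.Generator | int,
    mode: str = "profile",
    start: StartTimeModel | None = None,
    tail_policy: str = "extend",
) -> MisincorporationTable:
    """Simulate ``N`` independently copied templates of length ``L``."""
    if N < 1 or L < 1:
        raise ValueError("N and L must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if mode == "profile":
        prof = misincorporation_profile(kin, f, trace, L, start=start, tail_policy=tail_policy)
        x = rng.binomial(N, prof.probabilities)
        return MisincorporationTable(np.full(L, N), x)
    if mode == "event":
        x = np.zeros(L, dtype=np.int64)
        for _ in range(N):
            times = sample_incorporation_times(kin, L, rng, start=start)
            p = cmlf_eval(f, trace.value_at(times, tail_policy))
            x += rng.random(L) < p
        return MisincorporationTable(np.full(L, N), x)
    raise ValueError(f"unknown simulation mode {mode!r}")


def encode_word(word: str, seconds_per_letter: float) -> ConcentrationTrace:
    """Map an A-Z word to a piecewise-constant trace, letter k -> (k-1)/25."""
    if not word or not word.isalpha() or not word.isupper():
        raise ValueError("word must match [A-Z]+")
    if seconds_per_letter <= 0:
        raise ValueError("seconds_per_letter must be > 0")
    vals = np.array([(ord(ch) - ord("A")) / (_N_LETTERS - 1) for ch in word])
    dt = seconds_per_letter * 1000.0
    return ConcentrationTrace(TimeGrid(dt, dt * len(word)), vals)


def decode_word(trace_estimate: ConcentrationTrace) -> str:
    """Inverse of :func:`encode_word`: snap each bin to the nearest letter.

    Ties between two levels break toward the smaller letter.
    """
    levels = np.arange(_N_LETTERS) / (_N_LETTERS - 1)
    out = []
    for v in trace_estimate.values:
        k = int(np.argmin(np.abs(levels - v)))  # argmin takes first (smaller) on ties
        out.append(chr(ord("A") + k))
    return "".join(out)
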