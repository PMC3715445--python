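"""Analytic precision theory for a single concentration pulse.

For a square pulse of peak concentration ``C`` the per-position
misincorporation probability is ``E_i(C) = e0 + m C alpha_i`` where
``alpha_i`` is the probability that nucleotide i is replicated while the
pulse is on.  Each position of each template is a Bernoulli observation, so
the Fisher information about ``C`` is

    I(C) = N * sum_i (m alpha_i)^2 / (E_i (1 - E_i)),

additive over positions (independent misincorporations) and over templates
(independent copies).  Its inverse is the Cramér–Rao bound: the minimum
variance of any unbiased estimator of ``C``.  In the small-error limit the
``(1 - E_i)`` factor is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import PolymeraseKinetics, StartTimeModel
from .link import LinearCMLF, pulse_overlap_vector

__all__ = [
    "PulseSpec",
    "FisherResult",
    "fisher_information_full",
    "fisher_information_small_error",
    "crb_estimation_std",
]


@dataclass(frozen=True)
class PulseSpec:
    """Square concentration pulse: start ``t0`` (ms), duration ``dur`` (ms),
    peak scaled concentration ``conc`` in [0, 1]; zero elsewhere."""

    t0: float
    dur: float
    conc: float

    def __post_init__(self) -> None:
        if self.dur <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.t0 < 0:
            raise ValueError("pulse start must be >= 0")
        if not 0.0 <= self.conc <= 1.0:
            raise ValueError("pulse concentration must lie in [0, 1]")


@dataclass(frozen=True)
class FisherResult:
    info: float
    crb: float
    per_base_terms: np.ndarray = field(repr=False)
    alphas: np.ndarray = field(repr=False)


def _alphas(kin, pulse, L, start, method):
    return pulse_overlap_vector(
        kin, np.arange(1, L + 1), pulse.t0, pulse.dur, start=start, method=method
    )


def _result(terms: np.ndarray, alphas: np.ndarray, N: int) -> FisherResult:
    info = float(N * terms.sum())
    crb = 1.0 / info if info > 0 else np.inf
    return FisherResult(info=info, crb=crb, per_base_terms=terms, alphas=alphas)


def fisher_information_full(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    pulse: PulseSpec,
    N: int,
    L: int,
    start: StartTimeModel | None = None,
    method: str = "auto",
) -> FisherResult:
    """Exact Bernoulli Fisher information about the pulse concentration."""
    a = _alphas(kin, pulse, L, start, method)
    E = f.e0 + f.m * pulse.conc * a
    sing = (a > 0) & ((E <= 0) | (E >= 1))
    if np.any(sing):
        raise ValueError("E_i in {0, 1} at an informative position: Fisher information singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, (f.m * a) ** 2 / (E * (1.0 - E)), 0.0)
    return _result(terms, a, N)


def fisher_information_small_error(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    pulse: PulseSpec,
    N: int,
    L: int,
    start: StartTimeModel | None = None,
    method: str = "auto",
) -> FisherResult:
    """Small-misincorporation-rate approximation: drop the (1 - E_i) factor."""
    a = _alphas(kin, pulse, L, start, method)
    E = f.e0 + f.m * pulse.conc * a
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, (f.m * a) ** 2 / E, 0.0)
    if not np.all(np.isfinite(terms)):
        raise ValueError("E_i = 0 at an informative position: information singular")
    return _result(terms, a, N)


def crb_estimation_std(result: FisherResult) -> float:
    """sqrt of the Cramér–Rao bound; +inf for a totally uninformative signal."""
    if result.info <= 0:
        return np.inf
    return float(np.sqrt(1.0 / result.info))
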