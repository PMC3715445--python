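"""Concentration-to-misincorporation link and the forward model.

A linear concentration-to-misincorporation link function (CMLF)
``f(C) = e0 + m C`` maps the scaled ion concentration ``C`` (in [0, 1],
arbitrary units) to the per-base misincorporation probability.  Because the
time at which nucleotide i is added is random, its misincorporation
probability marginalizes the link over the incorporation-time distribution:

    E_i = sum_t f(C(t)) T_i(t) + tail_mass * f(C_tail)

with ``C_tail`` set by the tail policy ("extend" keeps the last trace value
beyond the recording, "zero" assumes the signal drops to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    IncorporationTimeDistribution,
    PolymeraseKinetics,
    StartTimeModel,
    TimeGrid,
    incorporation_mass_matrix,
)

__all__ = [
    "LinearCMLF",
    "ConcentrationTrace",
    "MisincorporationProfile",
    "cmlf_eval",
    "misincorporation_probability",
    "misincorporation_profile",
    "pulse_overlap",
]


@dataclass(frozen=True)
class LinearCMLF:
    """Linear link: baseline error rate ``e0``, slope ``m`` per unit concentration.

    The misincorporation rate at high (scaled) concentration is
    ``e_h = e0 + m``; ``m`` is the differential misincorporation rate.
    """

    e0: float
    m: float

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError("e0 must be >= 0")
        if self.e0 + max(self.m, 0.0) > 1.0 + 1e-12 or self.e0 + min(self.m, 0.0) < -1e-12:
            raise ValueError("e0 + m*C must stay in [0, 1] for all C in [0, 1]")

    @property
    def e_high(self) -> float:
        return self.e0 + self.m

    def __call__(self, c):
        return cmlf_eval(self, c)


def cmlf_eval(f: LinearCMLF, c):
    """Evaluate the link at concentration(s) ``c`` in [0, 1]."""
    c = np.asarray(c, dtype=float)
    if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
        raise ValueError("concentration must lie in [0, 1]")
    out = f.e0 + f.m * c
    return out if out.shape else float(out)


@dataclass(frozen=True)
class ConcentrationTrace:
    """Piecewise-constant scaled concentration on a uniform time grid."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.grid.n_bins:
            raise ValueError(
                f"trace needs one value per grid bin ({self.grid.n_bins}), got {v.size}"
            )
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("concentrations must lie in [0, 1]")

    @property
    def t_final(self) -> float:
        return self.grid.t_max

    def tail_value(self, tail_policy: str = "extend") -> float:
        if tail_policy == "extend":
            return float(self.values[-1])
        if tail_policy == "zero":
            return 0.0
        raise ValueError(f"unknown tail policy {tail_policy!r}")

    def value_at(self, t, tail_policy: str = "extend"):
        """Concentration at time(s) ``t`` (ms); beyond t_max per tail policy."""
        t = np.asarray(t, dtype=float)
        k = np.floor(t / self.grid.dt).astype(int)
        inside = (k >= 0) & (k < self.grid.n_bins)
        out = np.full(t.shape, self.tail_value(tail_policy))
        out[inside] = self.values[k[inside]]
        return out if out.shape else float(out)

    @staticmethod
    def constant(c: float, dt: float, t_max: float) -> "ConcentrationTrace":
        g = TimeGrid(dt, t_max)
        return ConcentrationTrace(g, np.full(g.n_bins, float(c)))


@dataclass(frozen=True)
class MisincorporationProfile:
    """Per-position misincorporation probabilities E_i, i = 1..L."""

    probabilities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.probabilities.size


def _check_compatible(tdist: IncorporationTimeDistribution, trace: ConcentrationTrace) -> int:
    """Trace bins may be coarser than the tdist grid by an integer factor."""
    ratio = trace.grid.dt / tdist.grid.dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"incompatible grids: trace dt={trace.grid.dt} is not an integer "
            f"multiple of distribution dt={tdist.grid.dt}"
        )
    return int(round(ratio))


def misincorporation_probability(
    tdist: IncorporationTimeDistribution,
    f: LinearCMLF,
    trace: ConcentrationTrace,
    tail_policy: str = "extend",
) -> float:
    """Marginalize the link over one incorporation-time distribution."""
    _check_compatible(tdist, trace)
    conc = trace.value_at(tdist.grid.centers, tail_policy)
    e = float(np.asarray(cmlf_eval(f, conc)) @ tdist.pmf)
    e += tdist.tail_mass * cmlf_eval(f, trace.tail_value(tail_policy))
    return e


def misincorporation_profile(
    kin: PolymeraseKinetics,
    f: LinearCMLF,
    trace: ConcentrationTrace,
    L: int,
    start: StartTimeModel | None = None,
    tail_policy: str = "extend",
    method: str = "auto",
) -> MisincorporationProfile:
    """E_i for i = 1..L under the exact/Gaussian kinetics policy.

    Piecewise-constant traces make the marginalization a matrix product with
    per-position bin masses, so the whole profile is computed at once.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    idx = np.arange(1, L + 1)
    M, tail = incorporation_mass_matrix(kin, idx, trace.grid.edges, start=start, method=method)
    probs = M @ np.asarray(cmlf_eval(f, trace.values)) + tail * cmlf_eval(
        f, trace.tail_value(tail_policy)
    )
    return MisincorporationProfile(probabilities=probs)


def pulse_overlap(
    kin: PolymeraseKinetics,
    i: int,
    t0: float,
    dur: float,
    start: StartTimeModel | None = None,
    method: str = "auto",
) -> float:
    """alpha_i: probability that nucleotide i is added during [t0, t0 + dur)."""
    if dur <= 0:
        raise ValueError("pulse duration must be > 0")
    if t0 < 0:
        raise ValueError("pulse start must be >= 0")
    a = pulse_overlap_vector(kin, np.array([i]), t0, dur, start=start, method=method)
    return float(a[0])


def pulse_overlap_vector(
    kin: PolymeraseKinetics,
    indices: np.ndarray,
    t0: float,
    dur: float,
    start: StartTimeModel | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Vectorized :func:`pulse_overlap` over nucleotide indices."""
    if t0 > 0:
        edges = np.array([0.0, t0, t0 + dur])
        col = 1
    else:
        edges = np.array([0.0, dur])
        col = 0
    M, _ = incorporation_mass_matrix(kin, indices, edges, start=start, method=method)
    return np.clip(M[:, col], 0.0, 1.0)
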