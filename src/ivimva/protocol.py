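"""PGSE acquisition geometry and b-value calculus.

A pulsed-gradient spin-echo (PGSE) diffusion experiment applies two
rectangular gradient pulses of amplitude ``G`` and duration ``delta``,
separated by the diffusion time ``Delta`` (onset to onset).  For such a
waveform the diffusion weighting is

    b = gamma^2 delta^2 G^2 (Delta - delta/3)

and the gradient first moment gives rise to the flow-sensitising
coefficient

    c = gamma G delta Delta = Delta * sqrt(b / (Delta - delta/3))

such that ``c * v`` is dimensionless for a blood speed ``v`` in mm/s.

Internal units are seconds and millimetres throughout: b in s/mm^2,
G in T/mm, gamma in rad/s/T, c in s/mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionPoint",
    "Protocol",
    "InvalidProtocolError",
    "compute_b",
    "gradient_for_b",
    "first_moment_c",
    "PAPER_B_VALUES",
    "PAPER_BIG_DELTAS",
    "PAPER_SMALL_DELTA",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8

#: The in-vivo acquisition grid: eight b-values (s/mm^2) ...
PAPER_B_VALUES = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)
#: ... crossed with four diffusion times (s) ...
PAPER_BIG_DELTAS = (0.0116, 0.020, 0.040, 0.050)
#: ... at fixed gradient duration (s).
PAPER_SMALL_DELTA = 0.0058


class InvalidProtocolError(ValueError):
    """Raised for physically impossible PGSE timing (delta <= 0 or Delta < delta)."""


def _check_timing(delta: float, Delta: float) -> None:
    if delta <= 0:
        raise InvalidProtocolError(f"gradient duration delta must be > 0, got {delta}")
    if Delta < delta:
        raise InvalidProtocolError(
            f"diffusion time Delta ({Delta}) must be >= gradient duration delta ({delta})"
        )


def compute_b(gamma: float, G: float, delta: float, Delta: float) -> float:
    """Diffusion weighting of a rectangular PGSE pair.

    Parameters
    ----------
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    G : float
        Gradient amplitude, T mm^-1 (must be >= 0).
    delta, Delta : float
        Pulse duration and onset-to-onset separation, s, with Delta >= delta.

    Returns
    -------
    float
        b = gamma^2 delta^2 G^2 (Delta - delta/3) in s mm^-2.
    """
    _check_timing(delta, Delta)
    if G < 0:
        raise ValueError(f"gradient amplitude must be >= 0, got {G}")
    return gamma**2 * delta**2 * G**2 * (Delta - delta / 3.0)


def gradient_for_b(b: float, delta: float, Delta: float, gamma: float = GAMMA_PROTON) -> float:
    """Unique non-negative gradient amplitude (T/mm) achieving a requested b."""
    _check_timing(delta, Delta)
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    return math.sqrt(b / (Delta - delta / 3.0)) / (gamma * delta)


def first_moment_c(b: float, delta: float, Delta: float) -> float:
    """Flow-encoding coefficient c = Delta * sqrt(b/(Delta - delta/3)), s mm^-1.

    Algebraically identical to gamma*G*delta*Delta for the G that realises
    b at this timing; c = 0 iff b = 0.
    """
    _check_timing(delta, Delta)
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    return Delta * math.sqrt(b / (Delta - delta / 3.0))


@dataclass(frozen=True)
class AcquisitionPoint:
    """One PGSE measurement: weighting, timing and gradient direction label."""

    b: float          # s mm^-2
    Delta: float      # s
    delta: float      # s
    direction: int = 0
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        _check_timing(self.delta, self.Delta)
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not 0 <= self.direction <= 2:
            raise ValueError(f"direction label must be in 0..2, got {self.direction}")

    @property
    def G(self) -> float:
        """Gradient amplitude (T/mm) realising b at this timing."""
        return gradient_for_b(self.b, self.delta, self.Delta, self.gamma)

    @property
    def c(self) -> float:
        """First-moment coefficient (s/mm); c*v is dimensionless."""
        return first_moment_c(self.b, self.delta, self.Delta)


@dataclass(frozen=True)
class Protocol:
    """An ordered collection of acquisition points plus scanner metadata."""

    points: tuple[AcquisitionPoint, ...]
    gamma: float = GAMMA_PROTON
    TE: float | None = None   # s, metadata only
    TR: float | None = None   # s, metadata only

    def __post_init__(self) -> None:
        # every distinct Delta must carry its own b=0 reference
        for Delta in self.big_deltas:
            if not any(p.b == 0 for p in self.points if p.Delta == Delta):
                raise InvalidProtocolError(f"no b=0 point for Delta={Delta}")

    @property
    def big_deltas(self) -> tuple[float, ...]:
        return tuple(sorted({p.Delta for p in self.points}))

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(sorted({p.b for p in self.points}))

    @property
    def max_gradient(self) -> float:
        """Largest gradient amplitude the protocol requires, T/mm."""
        return max(p.G for p in self.points)

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_grid(
        cls,
        b_values: Sequence[float] = PAPER_B_VALUES,
        big_deltas: Sequence[float] = PAPER_BIG_DELTAS,
        delta: float = PAPER_SMALL_DELTA,
        n_directions: int = 3,
        gamma: float = GAMMA_PROTON,
        TE: float | None = 0.06686,
        TR: float | None = 3.0,
    ) -> "Protocol":
        """Full factorial b x Delta x direction grid (default: the study grid)."""
        pts = tuple(
            AcquisitionPoint(b=float(b), Delta=float(D), delta=float(delta),
                             direction=d, gamma=gamma)
            for D in big_deltas
            for b in b_values
            for d in range(n_directions)
        )
        return cls(points=pts, gamma=gamma, TE=TE, TR=TR)


def make_default_protocol() -> Protocol:
    """The study acquisition: 8 b-values x 4 diffusion times x 3 directions.

    b in {0,10,20,50,100,200,500,1000} s/mm^2, Delta in {11.6,20,40,50} ms,
    delta = 5.8 ms, gradient amplitude solved per point to hold b fixed
    across diffusion times.
    """
    return Protocol.from_grid()
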