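"""Closed-form forward models of DW-MRI signal attenuation in microvessels.

The total signal follows a two-compartment description

    S(b)/S0 = f * exp(-b*Db) * H(b) + (1 - f) * exp(-b*D)

where ``f`` is the perfusion fraction, ``D`` the extravascular diffusion
coefficient, ``Db`` the apparent diffusivity of blood water, and ``H(b)``
the attenuation from incoherent blood flow through randomly oriented
capillary segments.  Four forms of ``H`` are provided, corresponding to
the flow regimes of intravoxel incoherent motion (IVIM):

``diffusive``
    Long diffusion times — blood changes segment (direction) many times
    during the encoding; H = exp(-b*Dstar) with pseudo-diffusion
    coefficient Dstar = v*l/6 (v blood speed, l segment length).
``ballistic_sinc``
    Short diffusion times — no direction change; H = sinc(c*v) with the
    unnormalised sinc sin(x)/x and c the gradient first-moment
    coefficient.
``va``
    Velocity-autocorrelation model: the blood velocity is a stationary
    process with exponential autocorrelation of correlation time T0,
    valid at all diffusion times and reducing to the two limits above.
``vab``
    Ballistic (T0 >> Delta) limit of the VA model:
    H = exp(-b v^2 Delta^2 / (6 (Delta - delta/3))) = exp(-(c*v)^2/6).

All quantities are in seconds and millimetres (b: s/mm^2, D: mm^2/s,
v: mm/s, l: mm, T0: s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionPoint, first_moment_c

__all__ = [
    "TissueState",
    "KernelTerms",
    "MODELS",
    "extravascular_attenuation",
    "ivim_diffusive_H",
    "ivim_ballistic_H",
    "va_kernel",
    "va_H",
    "vab_H",
    "total_signal",
    "pseudo_diffusion",
    "segment_length_from_dstar",
    "correlation_time_transit",
    "correlation_time_ivim",
]

#: Recognised labels for the intravascular attenuation model H(b).
MODELS = ("diffusive", "ballistic_sinc", "va", "vab")


def pseudo_diffusion(v: float, l: float) -> float:
    """Pseudo-diffusion coefficient Dstar = v*l/6 (mm^2/s)."""
    return v * l / 6.0


def segment_length_from_dstar(Dstar: float, v: float) -> float:
    """Invert Dstar = v*l/6 for the segment length l = 6*Dstar/v (mm)."""
    if v <= 0:
        raise ValueError("segment length undefined for v <= 0")
    return 6.0 * Dstar / v


def correlation_time_transit(l: float, v: float) -> float:
    """Segment transit time T0 = l/v (s).

    The literal reading of "time between directional changes": the time a
    blood element needs to traverse one segment.  Note this convention is
    NOT consistent with the diffusive limit of the VA model (see
    :func:`correlation_time_ivim`); the discrepancy is a factor of two.
    """
    if v <= 0:
        raise ValueError("transit time undefined for v <= 0")
    return l / v


def correlation_time_ivim(l: float, v: float) -> float:
    """Correlation time T0 = l/(2v) (s) consistent with Dstar = v*l/6.

    The VA model reduces to H = exp(-b*Dstar) with Dstar = v^2*T0/3 in the
    diffusive limit; equating with Dstar = v*l/6 gives T0 = l/(2v).
    """
    if v <= 0:
        raise ValueError("correlation time undefined for v <= 0")
    return l / (2.0 * v)


@dataclass
class TissueState:
    """Ground-truth physiological parameters of one tissue region.

    ``Dstar`` and ``T0`` may be left None and are derived from (v, l):
    Dstar = v*l/6 and T0 = l/(2v) (the convention consistent with the VA
    diffusive limit).
    """

    S0: float = 1.0        # unweighted signal, arbitrary units
    f: float = 0.08        # perfusion fraction
    D: float = 7.0e-4      # extravascular diffusivity, mm^2/s
    Db: float = 1.75e-3    # blood water apparent diffusivity, mm^2/s
    v: float = 2.0         # mean blood speed, mm/s
    l: float = 0.030       # mean segment length, mm
    T0: float | None = None     # velocity correlation time, s
    Dstar: float | None = None  # pseudo-diffusion coefficient, mm^2/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"perfusion fraction must be in [0,1], got {self.f}")
        for name in ("D", "Db", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.l <= 0:
            raise ValueError(f"segment length must be > 0, got {self.l}")
        if self.Dstar is None:
            self.Dstar = pseudo_diffusion(self.v, self.l)
        elif self.v > 0 and not math.isclose(self.Dstar, pseudo_diffusion(self.v, self.l),
                                             rel_tol=1e-9):
            raise ValueError("Dstar inconsistent with v*l/6")
        if self.T0 is None:
            self.T0 = correlation_time_ivim(self.l, self.v) if self.v > 0 else 1.0
        elif self.T0 <= 0:
            raise ValueError(f"T0 must be > 0, got {self.T0}")


@dataclass(frozen=True)
class KernelTerms:
    """Velocity-autocorrelation kernel terms for one PGSE timing.

    ``q`` is the dimensionless exponential sum, ``Omega`` the kernel
    factor (s^3) entering the VA exponent, and ``I = 2*T0*Omega`` the
    velocity-autocorrelation double integral at unit gamma*G (s^3).
    """

    q: float
    Omega: float
    I: float


def va_kernel(Delta: float, delta: float, T0: float) -> KernelTerms:
    """Exponential-autocorrelation kernel terms for a rectangular PGSE pair.

        q     = 2 e^{-Delta/T0} + 2 e^{-delta/T0}
                - e^{-(Delta+delta)/T0} - e^{-(Delta-delta)/T0} - 2
        Omega = delta^2 (Delta - delta/3) - 2 T0^2 delta - T0^3 q
        I     = 2 T0 Omega

    ``I`` equals the double integral of the gradient moment profile F(t)
    against the exponential velocity-correlation kernel e^{-|t-t'|/T0} at
    unit gamma*G.  Limits: Omega -> delta^2(Delta - delta/3) as T0 -> 0
    (diffusive) and T0*Omega -> Delta^2 delta^2 / 2 as T0 -> inf
    (ballistic).
    """
    if T0 <= 0:
        raise ValueError(f"correlation time T0 must be > 0, got {T0}")
    if delta <= 0 or Delta < delta:
        raise ValueError("require Delta >= delta > 0")
    x = Delta / T0
    y = delta / T0
    # Algebraically q = -4 e^{-x} sinh^2(y/2) + 2(e^{-y} - 1): identical to the
    # five-exponential sum but free of its catastrophic cancellation at large
    # T0.  The sinh form is itself cancellation-prone for y >> 1 (and would
    # overflow), so switch representation at y = 1; x >= y always.
    if y < 1.0:
        a2 = 4.0 * math.exp(-x) * math.sinh(0.5 * y) ** 2
    else:
        a2 = math.exp(y - x) - 2.0 * math.exp(-x) + math.exp(-x - y)
    q = -a2 + 2.0 * math.expm1(-y)
    # Omega = delta^2(Delta - delta/3) - 2 T0^2 delta - T0^3 q, regrouped so
    # the large-T0 cancellations happen analytically: g(y) = 1 - e^{-y} - y.
    g = -math.expm1(-y) - y
    Omega = delta**2 * (Delta - delta / 3.0) + T0**3 * (a2 + 2.0 * g)
    return KernelTerms(q=q, Omega=Omega, I=2.0 * T0 * Omega)


def extravascular_attenuation(b, D):
    """Monoexponential extravascular attenuation exp(-b*D)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(np.asarray(D) < 0):
        raise ValueError("b and D must be >= 0")
    return np.exp(-b * D)


def ivim_diffusive_H(b, Dstar):
    """Diffusive-regime intravascular attenuation H = exp(-b*Dstar)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(np.asarray(Dstar) < 0):
        raise ValueError("b and Dstar must be >= 0")
    return np.exp(-b * Dstar)


def ivim_ballistic_H(b, Delta, delta, v):
    """Ballistic-regime attenuation H = sinc(c*v), unnormalised sinc.

    May be negative beyond the first zero crossing c*v = pi; values are
    returned as-is (the fitting layer decides how to treat lobes).
    """
    if np.any(np.asarray(v) < 0):
        raise ValueError("v must be >= 0")
    b = np.asarray(b, dtype=float)
    c = np.vectorize(first_moment_c)(b, delta, Delta) if b.ndim else first_moment_c(float(b), delta, Delta)
    x = np.asarray(c, dtype=float) * v
    # np.sinc is the normalised sin(pi x)/(pi x); rescale for sin(x)/x
    return np.sinc(x / np.pi)


def va_H(b, Delta, delta, v, T0):
    """Velocity-autocorrelation attenuation (exponential correlation kernel).

    H = exp(-b * Omega * v^2 * T0 / (3 delta^2 (Delta - delta/3))).
    """
    if np.any(np.asarray(v) < 0):
        raise ValueError("v must be >= 0")
    k = va_kernel(Delta, delta, T0)
    b = np.asarray(b, dtype=float)
    denom = 3.0 * delta**2 * (Delta - delta / 3.0)
    return np.exp(-b * k.Omega * np.asarray(v) ** 2 * T0 / denom)


def vab_H(b, Delta, delta, v):
    """Ballistic limit of the VA model: H = exp(-b v^2 Delta^2 / (6(Delta - delta/3))).

    Identical to exp(-(c*v)^2 / 6) with c the first-moment coefficient.
    """
    if np.any(np.asarray(v) < 0):
        raise ValueError("v must be >= 0")
    if delta <= 0 or Delta < delta:
        raise ValueError("require Delta >= delta > 0")
    b = np.asarray(b, dtype=float)
    return np.exp(-b * np.asarray(v) ** 2 * Delta**2 / (6.0 * (Delta - delta / 3.0)))


def intravascular_H(b, Delta, delta, state: TissueState, model: str):
    """Dispatch H(b) for one of the labels in :data:`MODELS`."""
    if model == "diffusive":
        return ivim_diffusive_H(b, state.Dstar)
    if model == "ballistic_sinc":
        return ivim_ballistic_H(b, Delta, delta, state.v)
    if model == "va":
        return va_H(b, Delta, delta, state.v, state.T0)
    if model == "vab":
        return vab_H(b, Delta, delta, state.v)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def total_signal(point: AcquisitionPoint, state: TissueState, model: str):
    """Normalised two-compartment signal S/S0 at one acquisition point.

    S/S0 = f exp(-b Db) H(b) + (1-f) exp(-b D); equals 1 exactly at b=0.
    """
    H = intravascular_H(point.b, point.Delta, point.delta, state, model)
    return (state.f * np.exp(-point.b * state.Db) * H
            + (1.0 - state.f) * np.exp(-point.b * state.D))
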