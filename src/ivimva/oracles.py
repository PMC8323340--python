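"""Independent numerical oracles for the closed-form signal models.

Two physics checks that do not share code with the closed forms they
verify:

* ``pgse_b_numerical`` — the b-value as gamma^2 * int F(t)^2 dt with the
  explicit rectangular-pulse moment profile F(t), evaluated by adaptive
  quadrature; checks b = gamma^2 delta^2 G^2 (Delta - delta/3).
* ``kernel_integral_quadrature`` — the velocity-autocorrelation double
  integral I = dblint F(t) F(t') exp(-|t-t'|/T0) dt dt' at unit
  gamma*G, evaluated piecewise by 2-D adaptive quadrature; checks the
  closed form I = 2*T0*Omega and in particular the parenthesisation of
  Omega = delta^2(Delta - delta/3) - 2 T0^2 delta - T0^3 q.

Plus suite runners used by the ``oracle`` CLI subcommand and the
acceptance checks (kernel grid, Monte-Carlo regime limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import dblquad, quad

from .protocol import gradient_for_b, make_default_protocol
from .signal_models import ivim_ballistic_H, ivim_diffusive_H, pseudo_diffusion, va_kernel
from .simulate import VesselWalkConfig, walk_phase_integrals

__all__ = [
    "pgse_moment_profile",
    "pgse_b_numerical",
    "kernel_integral_quadrature",
    "kernel_quadrature_suite",
    "mc_regime_suite",
    "DEFAULT_KERNEL_GRID",
]


def pgse_moment_profile(delta: float, Delta: float):
    """F(t) = gamma*G * (accumulated gradient area) at unit gamma*G.

    Rises linearly over the first pulse [0, delta], stays flat on
    [delta, Delta], and falls back to zero over the refocused second
    pulse [Delta, Delta+delta].
    """
    def F(t: float) -> float:
        if t < 0.0:
            return 0.0
        if t < delta:
            return t
        if t < Delta:
            return delta
        if t < Delta + delta:
            return delta - (t - Delta)
        return 0.0
    return F


def pgse_b_numerical(gamma: float, G: float, delta: float, Delta: float) -> float:
    """b = gamma^2 G^2 * int_0^(Delta+delta) Fhat(t)^2 dt by quadrature."""
    F = pgse_moment_profile(delta, Delta)
    val, _ = quad(lambda t: F(t) ** 2, 0.0, Delta + delta,
                  points=[delta, Delta], limit=200, epsabs=0.0, epsrel=1e-12)
    return gamma**2 * G**2 * val


def kernel_integral_quadrature(Delta: float, delta: float, T0: float,
                               epsrel: float = 1e-10) -> float:
    """I = dblint F(t)F(s) e^{-|t-s|/T0} dt ds at unit gamma*G, by 2-D quadrature.

    The domain is split at the profile breakpoints and along the kernel
    kink t = s so every sub-integrand is smooth.  Computed internally in
    milliseconds for conditioning; the returned value is in s^3.
    """
    # work in ms
    d, D, t0 = delta * 1e3, Delta * 1e3, T0 * 1e3
    F = pgse_moment_profile(d, D)
    edges = sorted({0.0, d, D, D + d})
    pieces = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]

    def integrand(s, t):
        return F(t) * F(s) * math.exp(-(t - s) / t0)

    total = 0.0
    for i, (ai, bi) in enumerate(pieces):
        # diagonal block, s < t (doubled by symmetry)
        val, _ = dblquad(integrand, ai, bi, lambda t: ai, lambda t: t,
                         epsabs=1e-9, epsrel=epsrel)
        total += 2.0 * val
        # off-diagonal blocks with piece j entirely below piece i
        for (aj, bj) in pieces[:i]:
            val, _ = dblquad(integrand, ai, bi, lambda t: aj, lambda t: bj,
                             epsabs=1e-9, epsrel=epsrel)
            total += 2.0 * val
    return total * 1e-12  # F*F*dt*ds in ms^4 -> s^4 (= units of T0*Omega)


#: 5 x 5 x 5 (delta, Delta, T0) grid spanning the acquisition timings, s.
DEFAULT_KERNEL_GRID = (
    (0.0029, 0.00435, 0.0058, 0.00725, 0.0087),
    (0.0116, 0.020, 0.030, 0.040, 0.050),
    (0.001, 0.005, 0.015, 0.050, 0.200),
)


def kernel_quadrature_suite(grid=DEFAULT_KERNEL_GRID) -> dict:
    """Compare I = 2*T0*Omega with quadrature over the timing grid.

    Returns the maximum relative error and the number of grid points.
    """
    deltas, Deltas, T0s = grid
    max_rel = 0.0
    n = 0
    for d in deltas:
        for D in Deltas:
            if D < d:
                continue
            for T0 in T0s:
                closed = va_kernel(D, d, T0).I
                numeric = kernel_integral_quadrature(D, d, T0)
                rel = abs(closed - numeric) / abs(numeric)
                max_rel = max(max_rel, rel)
                n += 1
    return {"max_rel_err": max_rel, "n_points": n}


def mc_regime_suite(n_spins: int = 100_000, seed: int = 0,
                    v: float = 2.0, b_max: float = 500.0) -> dict:
    """Monte-Carlo vs closed forms in the two limiting flow regimes.

    Ballistic configuration l = 100*v*Delta vs sinc(c v); diffusive
    configuration l = v*Delta/50 (restricted to b*Dstar < 0.5) vs
    exp(-b v l / 6).  One trajectory ensemble is simulated per
    (regime, Delta) and re-weighted across b through the gradient
    amplitude, so every protocol point with 0 < b < ``b_max`` is
    checked.  Returns the worst |z| = |H_mc - H_model| / SE per regime.
    """
    protocol = make_default_protocol()
    pairs = sorted({(p.b, p.Delta, p.delta) for p in protocol
                    if 0.0 < p.b < b_max})
    out = {"ballistic": [], "diffusive": []}
    for regime in ("ballistic", "diffusive"):
        for Delta in sorted({D for _, D, _ in pairs}):
            delta = next(dd for _, D, dd in pairs if D == Delta)
            l = 100.0 * v * Delta if regime == "ballistic" else v * Delta / 50.0
            cfg = VesselWalkConfig(n_spins=n_spins, l=l, v=v, Delta=Delta,
                                   delta=delta, G=1.0, seed=seed)
            psi = walk_phase_integrals(cfg)
            for b, D, dd in pairs:
                if D != Delta:
                    continue
                Dstar = pseudo_diffusion(v, l)
                if regime == "diffusive" and b * Dstar >= 0.5:
                    continue
                G = gradient_for_b(b, dd, D)
                phi = cfg.gamma * G * psi
                cosphi = np.cos(phi)
                H_mc = float(np.mean(cosphi))
                se = float(np.std(cosphi, ddof=1) / math.sqrt(n_spins))
                if regime == "ballistic":
                    H_model = float(ivim_ballistic_H(b, D, dd, v))
                else:
                    H_model = float(ivim_diffusive_H(b, Dstar))
                out[regime].append({"b": b, "Delta": D, "H_mc": H_mc,
                                    "H_model": H_model, "se": se,
                                    "z": (H_mc - H_model) / se})
    return {
        "ballistic_max_abs_z": max(abs(r["z"]) for r in out["ballistic"]),
        "diffusive_max_abs_z": max(abs(r["z"]) for r in out["diffusive"]),
        "n_ballistic": len(out["ballistic"]),
        "n_diffusive": len(out["diffusive"]),
        "records": out,
    }
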