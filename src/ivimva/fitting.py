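"""Two-step IVIM estimation pipeline.

Stage 1 (extravascular): for each diffusion time the extravascular
diffusivity ``D`` is estimated from the two highest b-values, where the
intravascular contribution is negligible,

    D = ln(S2/S1) / (b1 - b2),

and the perfusion fraction from

    f = 1 - (S/S0) * exp(b*D),

evaluated at both high b-values and averaged.

Stage 2 (intravascular): the extravascular component is subtracted and
the remainder divided by ``f`` to isolate the intravascular signal,

    y(b) = (1/f) * (S/S0 - (1-f) * exp(-b*D)),

which is then fitted (b < 500 s/mm^2, trust-region-reflective nonlinear
least squares) with ``y = exp(-b*Db) * H(b) + d`` where ``d`` is an
intercept nuisance parameter absorbing two-step bias:

* the diffusive IVIM form at the longest diffusion time gives ``Dstar``;
* the sinc (IVIM ballistic) and Gaussian (VAB) forms at the shortest
  diffusion time give ``v`` (one estimate per method);
* the velocity-autocorrelation (VA) form is fitted jointly across all
  diffusion times, giving ``v`` and the correlation time ``T0``.

Segment lengths follow as l = 6*Dstar/v for each velocity method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .signal_models import (
    ivim_ballistic_H,
    segment_length_from_dstar,
    va_kernel,
    vab_H,
)

__all__ = [
    "SignalTable",
    "FitConfig",
    "SingleFit",
    "FitResult",
    "average_directions",
    "estimate_D",
    "estimate_f",
    "isolate_intravascular",
    "fit_diffusive",
    "fit_ballistic",
    "fit_va",
    "segment_length",
    "run_pipeline",
]

VELOCITY_METHODS = ("ivim_ballistic", "va", "vab")

_REQUIRED = ["subject", "session", "region", "b", "Delta", "delta", "direction", "signal"]


@dataclass
class SignalTable:
    """ROI-averaged DW-MRI signals in internal units (b: s/mm^2, times: s).

    Wraps a tidy DataFrame with columns
    ``subject, session, region, b, Delta, delta, direction, signal``
    (extra columns such as ``strain`` are carried through untouched).
    Each (subject, session, region, Delta) group must contain a b = 0
    record, which serves as the S0 reference.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"SignalTable missing required columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        if (self.data["signal"] < 0).any():
            bad = self.data.index[self.data["signal"] < 0].tolist()
            raise ValueError(f"negative signals at rows {bad[:10]}")
        if (self.data["b"] < 0).any():
            raise ValueError("negative b-values present")
        if (self.data["Delta"] < self.data["delta"]).any():
            raise ValueError("rows with Delta < delta present")
        missing_b0 = []
        for key, grp in self.data.groupby(["subject", "session", "region", "Delta"], sort=False):
            if not (grp["b"] == 0).any():
                missing_b0.append(key)
        if missing_b0:
            raise ValueError(f"groups lacking a b=0 record: {missing_b0[:10]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def regions(self) -> list:
        return sorted(self.data["region"].unique())


def average_directions(table: SignalTable) -> SignalTable:
    """Mean over gradient directions; idempotent.

    Collapses to one record per (subject, session, region, Delta, b),
    keeping first-seen values of any extra grouping columns (e.g. strain).
    """
    df = table.data
    if df.empty:
        raise ValueError("cannot average an empty table")
    keys = ["subject", "session", "region", "Delta", "delta", "b"]
    extra = [c for c in df.columns if c not in keys + ["direction", "signal"]]
    agg = {"signal": "mean", **{c: "first" for c in extra}}
    out = df.groupby(keys, as_index=False, sort=True).agg(agg)
    out["direction"] = -1  # sentinel: direction-averaged
    return SignalTable(out)


def estimate_D(S_b1: float, S_b2: float, b1: float, b2: float) -> float:
    """Extravascular diffusivity from two high-b signals: D = ln(S2/S1)/(b1-b2)."""
    if S_b1 <= 0 or S_b2 <= 0:
        raise ValueError("high-b signals must be positive")
    if b1 == b2:
        raise ValueError("b1 and b2 must differ")
    return math.log(S_b2 / S_b1) / (b1 - b2)


def estimate_f(S: float, S0: float, b: float, D: float) -> float:
    """Perfusion fraction at one b-value: f = 1 - (S/S0) * exp(b*D).  Unclipped."""
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    return 1.0 - (S / S0) * math.exp(b * D)


@dataclass
class FitConfig:
    """Tunable pipeline settings (defaults reproduce the study analysis)."""

    b_high: tuple[float, float] = (500.0, 1000.0)   # D and f estimation, s/mm^2
    b_intra_max: float = 500.0                       # intravascular fits use b < this
    diffusive_Delta: float | None = 0.050            # s; None -> longest available
    ballistic_Delta: float | None = 0.0116           # s; None -> shortest available
    Db: float = 1.75e-3                              # blood ADC, mm^2/s (fixed)
    f_min: float = 0.005                             # below this the region is skipped
    v_bounds: tuple[float, float] = (0.0, 20.0)      # mm/s
    v_init: float = 1.0
    T0_bounds: tuple[float, float] = (1.0e-4, 1.0)   # s
    T0_init: float = 0.015
    Dstar_bounds: tuple[float, float] = (0.0, 0.1)   # mm^2/s
    Dstar_init: float = 5.0e-3
    d_bounds: tuple[float, float] = (-0.5, 0.5)
    d_init: float = 0.0
    t0_rel_se_flag: float = 10.0   # flag T0 when se(T0)/T0 exceeds this

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class SingleFit:
    """Outcome of one nonlinear least-squares fit."""

    params: dict
    rss: float
    n_points: int
    converged: bool
    flags: list = field(default_factory=list)


@dataclass
class FitResult:
    """Per-(subject, session, region) parameter estimates with diagnostics."""

    subject: object
    session: object
    region: object
    D: dict = field(default_factory=dict)       # Delta -> mm^2/s
    f: dict = field(default_factory=dict)       # Delta -> fraction
    Dstar: float = float("nan")                 # mm^2/s, from diffusive Delta
    d_diffusive: float = float("nan")
    v: dict = field(default_factory=dict)       # method -> mm/s
    d: dict = field(default_factory=dict)       # method -> intercept
    T0: float = float("nan")                    # s, VA fit only
    l: dict = field(default_factory=dict)       # method -> mm
    rss: dict = field(default_factory=dict)     # fit label -> residual sum of squares
    n_points: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_record(self) -> dict:
        rec = {"subject": self.subject, "session": self.session, "region": self.region,
               "Dstar": self.Dstar, "T0_va": self.T0, "d_diffusive": self.d_diffusive}
        for Delta, val in sorted(self.D.items()):
            rec[f"D_Delta{round(Delta * 1e3, 3)}ms"] = val
        for Delta, val in sorted(self.f.items()):
            rec[f"f_Delta{round(Delta * 1e3, 3)}ms"] = val
        for m in VELOCITY_METHODS:
            rec[f"v_{m}"] = self.v.get(m, float("nan"))
            rec[f"l_{m}"] = self.l.get(m, float("nan"))
            rec[f"d_{m}"] = self.d.get(m, float("nan"))
        rec["flags"] = ";".join(self.flags)
        return rec


def isolate_intravascular(group: pd.DataFrame, f: float, D: float,
                          Db: float, b_max: float) -> pd.DataFrame:
    """Isolate the intravascular fraction for one (region, Delta) group.

    Returns the b < ``b_max`` records with a column ``y`` holding
    (1/f) * (S/S0 - (1-f) e^{-b D}).  ``y`` may go negative under noise
    and is deliberately not clamped.  ``Db`` is carried for the model
    side e^{-b Db} H + d and is not used in the isolation itself.
    """
    if f <= 0:
        raise ValueError("cannot isolate intravascular component with f <= 0")
    s0_rows = group.loc[group["b"] == 0, "signal"]
    if s0_rows.empty:
        raise ValueError("group lacks a b=0 reference")
    S0 = float(s0_rows.mean())
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    sub = group[group["b"] < b_max].copy()
    snorm = sub["signal"] / S0
    sub["y"] = (snorm - (1.0 - f) * np.exp(-sub["b"] * D)) / f
    return sub


def _ls(fun: Callable, x0, bounds, x_scale) -> tuple[np.ndarray, float, bool]:
    res = least_squares(fun, x0=np.asarray(x0, dtype=float),
                        bounds=bounds, method="trf", x_scale=x_scale,
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
    return res.x, float(res.cost * 2.0), bool(res.success)


def _near_bound(x: float, lo: float, hi: float) -> bool:
    span = hi - lo
    return (x - lo) <= 1e-6 * span or (hi - x) <= 1e-6 * span


def fit_diffusive(b: np.ndarray, y: np.ndarray, config: FitConfig) -> SingleFit:
    """Fit y = exp(-b (Db + Dstar)) + d on the long-diffusion-time series."""
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(b) < 4:
        raise ValueError("need at least 4 points for the diffusive fit")

    def resid(p):
        Dstar, d = p
        return np.exp(-b * (config.Db + Dstar)) + d - y

    lo = [config.Dstar_bounds[0], config.d_bounds[0]]
    hi = [config.Dstar_bounds[1], config.d_bounds[1]]
    x, rss, ok = _ls(resid, [config.Dstar_init, config.d_init], (lo, hi),
                     x_scale=[1e-3, 0.1])
    flags = []
    if not ok:
        flags.append("diffusive_fit_not_converged")
    if _near_bound(x[0], *config.Dstar_bounds):
        flags.append("dstar_at_bound")
    return SingleFit(params={"Dstar": x[0], "d": x[1]}, rss=rss,
                     n_points=len(b), converged=ok, flags=flags)


def fit_ballistic(b: np.ndarray, y: np.ndarray, Delta: float, delta: float,
                  method: str, config: FitConfig) -> SingleFit:
    """Fit y = exp(-b Db) H(b; v) + d at a single short diffusion time.

    ``method`` selects H: ``"ivim_ballistic"`` (sinc(c v), negative lobes
    allowed) or ``"vab"`` (Gaussian exp(-(c v)^2/6)).
    """
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(b) < 4:
        raise ValueError("need at least 4 points for the ballistic fit")
    if method == "ivim_ballistic":
        Hfun = lambda v: ivim_ballistic_H(b, Delta, delta, v)
    elif method == "vab":
        Hfun = lambda v: vab_H(b, Delta, delta, v)
    else:
        raise ValueError(f"unknown ballistic method {method!r}")

    atten = np.exp(-b * config.Db)

    def resid(p):
        v, d = p
        return atten * Hfun(v) + d - y

    lo = [config.v_bounds[0], config.d_bounds[0]]
    hi = [config.v_bounds[1], config.d_bounds[1]]
    x, rss, ok = _ls(resid, [config.v_init, config.d_init], (lo, hi),
                     x_scale=[1.0, 0.1])
    flags = []
    if not ok:
        flags.append(f"{method}_fit_not_converged")
    if _near_bound(x[0], *config.v_bounds) and x[0] > 0:
        flags.append(f"{method}_v_at_bound")
    if method == "ivim_ballistic":
        from .protocol import first_moment_c
        cmax = max(first_moment_c(float(bb), delta, Delta) for bb in b)
        if cmax * x[0] >= math.pi:
            flags.append("cv_exceeds_pi")
    return SingleFit(params={"v": x[0], "d": x[1]}, rss=rss,
                     n_points=len(b), converged=ok, flags=flags)


def fit_va(b: np.ndarray, y: np.ndarray, Delta: np.ndarray, delta: float,
           config: FitConfig) -> SingleFit:
    """Joint velocity-autocorrelation fit across diffusion times.

    y = exp(-b Db) exp(-b Omega(Delta, delta, T0) v^2 T0 / (3 delta^2
    (Delta - delta/3))) + d with a single shared intercept d.
    """
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    deltas_distinct = np.unique(Delta)
    if len(b) < 4:
        raise ValueError("need at least 4 points for the VA fit")
    atten = np.exp(-b * config.Db)
    denom = 3.0 * delta**2 * (Delta - delta / 3.0)

    def model(v, T0):
        Omega = np.array([va_kernel(D, delta, T0).Omega for D in deltas_distinct])
        Omega_full = Omega[np.searchsorted(deltas_distinct, Delta)]
        return atten * np.exp(-b * Omega_full * v**2 * T0 / denom)

    def resid(p):
        v, T0, d = p
        return model(v, T0) + d - y

    lo = [config.v_bounds[0], config.T0_bounds[0], config.d_bounds[0]]
    hi = [config.v_bounds[1], config.T0_bounds[1], config.d_bounds[1]]
    x, rss, ok = _ls(resid, [config.v_init, config.T0_init, config.d_init],
                     (lo, hi), x_scale=[1.0, 0.01, 0.1])
    v, T0, d = x
    flags = []
    if not ok:
        flags.append("va_fit_not_converged")
    if _near_bound(T0, *config.T0_bounds):
        flags.append("va_T0_at_bound")
    if len(deltas_distinct) < 2:
        flags.append("t0_poorly_identified")
    else:
        # crude identifiability check via the Gauss-Newton covariance
        eps = np.array([1e-6, 1e-8, 1e-8])
        J = np.empty((len(b), 3))
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps[j]
            J[:, j] = (resid(x + step) - resid(x - step)) / (2 * eps[j])
        dof = max(len(b) - 3, 1)
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            se_T0 = math.sqrt(max(cov[1, 1], 0.0))
            if T0 > 0 and se_T0 / T0 > config.t0_rel_se_flag:
                flags.append("t0_poorly_identified")
        except np.linalg.LinAlgError:
            flags.append("t0_poorly_identified")
    return SingleFit(params={"v": v, "T0": T0, "d": d}, rss=rss,
                     n_points=len(b), converged=ok, flags=flags)


def segment_length(Dstar: float, v: float) -> float:
    """Segment length l = 6*Dstar/v (mm); undefined (raises) for v <= 0."""
    return segment_length_from_dstar(Dstar, v)


def _nearest(available: np.ndarray, target: float) -> float:
    return float(available[np.argmin(np.abs(available - target))])


def run_pipeline(table: SignalTable, config: FitConfig | None = None) -> list[FitResult]:
    """Run the full two-step pipeline on every (subject, session, region).

    Deterministic given inputs and config; a group failing one stage
    carries partial results plus diagnostic flags, never aborting others.
    """
    config = config or FitConfig()
    averaged = average_directions(table) if not table.data.empty else table
    results: list[FitResult] = []
    if table.data.empty:
        return results
    b1, b2 = config.b_high
    for (subject, session, region), grp in averaged.data.groupby(
            ["subject", "session", "region"], sort=True):
        res = FitResult(subject=subject, session=session, region=region)
        deltas = np.sort(grp["Delta"].unique())
        delta_small = float(grp["delta"].iloc[0])
        series = {}   # Delta -> isolated DataFrame
        for Delta in deltas:
            g = grp[grp["Delta"] == Delta]
            S0 = float(g.loc[g["b"] == 0, "signal"].mean())
            try:
                s_at = {bb: float(g.loc[g["b"] == bb, "signal"].iloc[0])
                        for bb in (b1, b2)}
            except IndexError:
                res.flags.append(f"missing_high_b_Delta{Delta}")
                continue
            try:
                D = estimate_D(s_at[b1], s_at[b2], b1, b2)
            except ValueError:
                res.flags.append(f"nonpositive_high_b_signal_Delta{Delta}")
                res.D[float(Delta)] = float("nan")
                continue
            f_vals = [estimate_f(s_at[bb], S0, bb, D) for bb in (b1, b2)]
            f = float(np.mean(f_vals))
            if f < 0.0 or f > 1.0:
                res.flags.append(f"f_clipped_Delta{Delta}")
                f = min(max(f, 0.0), 1.0)
            res.D[float(Delta)] = D
            res.f[float(Delta)] = f
            if f <= config.f_min:
                res.flags.append(f"f_below_min_Delta{Delta}")
                continue
            series[float(Delta)] = isolate_intravascular(
                g, f=f, D=D, Db=config.Db, b_max=config.b_intra_max)

        # --- diffusive regime: Dstar from the longest diffusion time ---
        target_diff = config.diffusive_Delta if config.diffusive_Delta is not None \
            else (deltas.max() if len(deltas) else None)
        diff_Delta = None
        if target_diff is not None and series:
            cand = np.array(sorted(series))
            diff_Delta = _nearest(cand, target_diff)
            if not math.isclose(diff_Delta, target_diff, rel_tol=1e-6):
                diff_Delta = None
        if diff_Delta is None:
            res.flags.append("missing_diffusive_delta")
        else:
            s = series[diff_Delta]
            try:
                fit = fit_diffusive(s["b"].to_numpy(), s["y"].to_numpy(), config)
                res.Dstar = fit.params["Dstar"]
                res.d_diffusive = fit.params["d"]
                res.rss["diffusive"] = fit.rss
                res.n_points["diffusive"] = fit.n_points
                res.flags += fit.flags
            except ValueError as exc:
                res.flags.append(f"diffusive_fit_error:{exc}")

        # --- ballistic regime: v from the shortest diffusion time ---
        target_ball = config.ballistic_Delta if config.ballistic_Delta is not None \
            else (deltas.min() if len(deltas) else None)
        ball_Delta = None
        if target_ball is not None and series:
            cand = np.array(sorted(series))
            ball_Delta = _nearest(cand, target_ball)
            if not math.isclose(ball_Delta, target_ball, rel_tol=1e-6):
                ball_Delta = None
        if ball_Delta is None:
            res.flags.append("missing_ballistic_delta")
        else:
            s = series[ball_Delta]
            for method in ("ivim_ballistic", "vab"):
                try:
                    fit = fit_ballistic(s["b"].to_numpy(), s["y"].to_numpy(),
                                        ball_Delta, delta_small, method, config)
                    res.v[method] = fit.params["v"]
                    res.d[method] = fit.params["d"]
                    res.rss[method] = fit.rss
                    res.n_points[method] = fit.n_points
                    res.flags += fit.flags
                except ValueError as exc:
                    res.flags.append(f"{method}_fit_error:{exc}")

        # --- VA model: joint fit across all diffusion times ---
        if series:
            allb = np.concatenate([s["b"].to_numpy() for s in series.values()])
            ally = np.concatenate([s["y"].to_numpy() for s in series.values()])
            allD = np.concatenate([np.full(len(s), Delta)
                                   for Delta, s in series.items()])
            try:
                fit = fit_va(allb, ally, allD, delta_small, config)
                res.v["va"] = fit.params["v"]
                res.T0 = fit.params["T0"]
                res.d["va"] = fit.params["d"]
                res.rss["va"] = fit.rss
                res.n_points["va"] = fit.n_points
                res.flags += fit.flags
            except ValueError as exc:
                res.flags.append(f"va_fit_error:{exc}")
        else:
            res.flags.append("no_intravascular_series")

        # --- segment lengths l = 6 Dstar / v ---
        for method, v in res.v.items():
            if math.isnan(res.Dstar):
                res.flags.append(f"l_missing_no_dstar_{method}")
            elif v <= 0:
                res.flags.append(f"l_undefined_v_zero_{method}")
            else:
                res.l[method] = segment_length(res.Dstar, v)
        results.append(res)
    return results


def results_to_frame(results: Iterable[FitResult]) -> pd.DataFrame:
    """Flatten FitResults to a tidy DataFrame (one row per subject/session/region)."""
    recs = [r.to_record() for r in results]
    return pd.DataFrame(recs)
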