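"""Hill binding parameters, the governing ODE and a numerical oracle.

The receptor R binds ``n`` signal molecules S at once,

    n S + R  <-> R S_n      (association k1, dissociation k2),

and the bound fraction P(t) = [RS_n] / ([R] + [RS_n]) obeys

    dP/dt = (1 - P) k1 [S]^n - k2 P,

assuming the signal pool is not depleted by binding ([S] >> [R]).  Under a
square-wave signal [S] is piecewise constant, so within each on- or
off-segment the ODE is linear with constant coefficients and the exact
update is a single exponential relaxation.  ``integrate_numeric`` chains
those exact per-segment updates and serves as the oracle against which the
closed-form trajectory expressions are validated; an adaptive Runge-Kutta
integration restarted at every pulse edge is available as a secondary
cross-check (``method="adaptive"``).

Units: concentrations nM, times h, k1 in nM^-n h^-1, k2 in h^-1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .signal import SquareWaveSignal

__all__ = [
    "HillParameters",
    "BindingTrajectory",
    "binding_rate",
    "integrate_numeric",
]


@dataclass(frozen=True)
class HillParameters:
    """Hill coefficient and rate constants for cooperative binding.

    ``K_d = K_A^n = k2 / k1`` ties the dissociation equilibrium constant
    ``K_d`` (nM^n) and the dissociation constant ``K_A`` (nM) to the rate
    constants.  Construct either directly from ``(n, k1, k2)`` or from
    ``(n, k1, K_A)`` via :meth:`from_dissociation_constant`.
    """

    n: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not self.n >= 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        if not self.k1 > 0:
            raise ValueError(f"k1 must be > 0, got {self.k1}")
        if not self.k2 >= 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")

    @classmethod
    def from_dissociation_constant(
        cls, n: float, k1: float, K_A: float
    ) -> "HillParameters":
        """Build from ``K_A`` (nM), deriving ``k2 = k1 * K_A**n``."""
        if not K_A >= 0:
            raise ValueError(f"K_A must be >= 0, got {K_A}")
        return cls(n=n, k1=k1, k2=k1 * K_A**n)

    @property
    def K_d(self) -> float:
        """Dissociation equilibrium constant ``k2 / k1`` in nM^n."""
        return self.k2 / self.k1

    @property
    def K_A(self) -> float:
        """Dissociation constant ``(k2 / k1)^(1/n)`` in nM."""
        return (self.k2 / self.k1) ** (1.0 / self.n)

    def on_rate(self, S: float) -> float:
        """Total relaxation rate ``k1 S^n + k2`` (h^-1) at constant [S]=S."""
        return self.k1 * S**self.n + self.k2


def binding_rate(params: HillParameters, P: float, S: float) -> float:
    """Right-hand side of the binding ODE, ``(1-P) k1 S^n - k2 P`` (h^-1)."""
    if not 0 <= P <= 1:
        raise ValueError(f"P must lie in [0, 1], got {P}")
    if not S >= 0:
        raise ValueError(f"S must be >= 0, got {S}")
    return (1.0 - P) * params.k1 * S**params.n - params.k2 * P


@dataclass(frozen=True)
class BindingTrajectory:
    """Sampled binding probability P(t) under a square-wave signal."""

    times: np.ndarray
    probabilities: np.ndarray
    signal: SquareWaveSignal
    params: HillParameters

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and probabilities must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", p)

    def pulse_index(self) -> np.ndarray:
        """1-based pulse index of every sample."""
        return self.signal.pulse_phase(self.times)[0]

    def phase(self) -> np.ndarray:
        """Phase xi (time since pulse start, h) of every sample."""
        return self.signal.pulse_phase(self.times)[1]

    # -- CSV round trip -------------------------------------------------
    # Columns time_h, signal_nM, P; '#'-prefixed header lines carry the
    # full parameter set as JSON so a trajectory file is self-describing.

    def to_csv(self, path_or_buf) -> None:
        meta = {
            "n": self.params.n,
            "k1_per_nM_n_per_h": self.params.k1,
            "k2_per_h": self.params.k2,
            "K_A_nM": self.params.K_A,
            "amplitude_nM": self.signal.amplitude,
            "period_h": self.signal.period,
            "duty_cycle": self.signal.duty_cycle,
        }
        lines = [f"# {json.dumps(meta)}", "time_h,signal_nM,P"]
        s = self.signal.concentration(self.times)
        for t, sv, p in zip(self.times, s, self.probabilities):
            lines.append(f"{t:.12g},{sv:.12g},{p:.12g}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "BindingTrajectory":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta = None
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = json.loads(line[1:])
            elif not line.startswith("time_h"):
                rows.append([float(x) for x in line.split(",")])
        if meta is None:
            raise ValueError("trajectory CSV is missing its '#' metadata header")
        arr = np.asarray(rows, dtype=float)
        params = HillParameters(meta["n"], meta["k1_per_nM_n_per_h"], meta["k2_per_h"])
        sig = SquareWaveSignal(meta["amplitude_nM"], meta["period_h"], meta["duty_cycle"])
        return cls(times=arr[:, 0], probabilities=arr[:, 2], signal=sig, params=params)


def _output_times(signal: SquareWaveSignal, t_end: float, dt_out: float) -> np.ndarray:
    """Multiples of dt_out up to t_end, plus every pulse edge and t_end."""
    ts = [np.arange(0.0, t_end + 0.5 * dt_out, dt_out)]
    n_periods = int(math.floor(t_end / signal.period)) + 1
    starts = np.arange(n_periods + 1) * signal.period
    ts.append(starts)
    if not signal.is_sustained:
        ts.append(starts + signal.pulse_on)
    t = np.unique(np.concatenate(ts))
    t = t[(t >= 0) & (t <= t_end)]
    if t[-1] < t_end:
        t = np.append(t, t_end)
    # merge float near-duplicates (k*dt_out vs an exact pulse edge)
    keep = np.ones(t.size, dtype=bool)
    keep[1:] = np.diff(t) > 1e-12 * np.maximum(1.0, t[1:])
    return t[keep]


def integrate_numeric(
    params: HillParameters,
    signal: SquareWaveSignal,
    t_end: float,
    P0: float = 0.0,
    dt_out: float | None = None,
    method: str = "exact",
) -> BindingTrajectory:
    """Integrate the binding ODE under the square-wave signal.

    The output grid is every multiple of ``dt_out`` (default ``T/200``)
    plus all pulse edges and ``t_end``; integration restarts exactly at
    every pulse edge so no edge is stepped over.

    method="exact" (the oracle) applies the closed-form exponential update
    on each constant-signal segment: with rate ``r = k1 S^n + k2`` and fixed
    point ``P* = k1 S^n / r``,

        P(t0 + h) = P* + (P(t0) - P*) exp(-r h).

    method="adaptive" uses RK45 (rtol 1e-10) per segment as an independent
    cross-check.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if not 0 <= P0 <= 1:
        raise ValueError(f"P0 must lie in [0, 1], got {P0}")
    if dt_out is None:
        dt_out = signal.period / 200.0
    if not dt_out > 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")

    t = _output_times(signal, t_end, dt_out)
    p = np.empty_like(t)
    p[0] = P0
    cur = P0
    for j in range(1, len(t)):
        t0, t1 = t[j - 1], t[j]
        # [S] is constant on [t0, t1) because all edges are grid nodes;
        # sample it at the midpoint, which is immune to the float rounding
        # of t0 % T at exact pulse edges.
        S = signal.concentration(0.5 * (t0 + t1))
        h = t1 - t0
        if method == "exact":
            r = params.on_rate(S)
            if r == 0.0:
                pass  # S = 0 and k2 = 0: P is constant
            else:
                p_star = params.k1 * S**params.n / r
                cur = p_star + (cur - p_star) * math.exp(-r * h)
        elif method == "adaptive":
            sol = solve_ivp(
                lambda _t, y, S=S: [
                    (1.0 - y[0]) * params.k1 * S**params.n - params.k2 * y[0]
                ],
                (t0, t1),
                [cur],
                method="RK45",
                rtol=1e-10,
                atol=1e-13,
            )
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"ODE integration failed at t={t0}: {sol.message}")
            cur = float(sol.y[0, -1])
        else:
            raise ValueError(f"unknown method {method!r}")
        p[j] = cur
    # The exact update cannot leave [0, 1]; clip only float dust.
    p = np.clip(p, 0.0, 1.0)
    return BindingTrajectory(times=t, probabilities=p, signal=signal, params=params)
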