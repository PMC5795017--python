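"""Pulsing-regime classification, rise times and regime boundaries.

The decisive dimensionless number is ``x = k2 (1 - gamma) T``: the length
of the signal-off phase measured in units of the unbinding time 1/k2.

    x >> 1  (slow pulsing, regime d): binding fully tracks the signal;
    x ~  1  (competitive pulsing, regime e): unbinding competes with the
            pulse train and binding outlasts each pulse;
    x << 1  (fast pulsing, regime f): binding barely ripples within a
            period and responds to the average drive.

Within regime f a still-stronger condition (k2 T << 1 - k1 A^n gamma T,
requiring k1 A^n gamma T << 1) produces *graded clocking* (regime g): each
pulse deposits nearly the same increment of binding, so the bound level
counts pulses.  The qualitative "much greater/less than" comparisons are
made operational with a symmetric factor-of-10 threshold (configurable),
and "<<" in the graded conditions with a factor epsilon = 0.1.

Fast pulsing can also *slow down* high-affinity binding: the pulse-averaged
rise time

    tau_pulsed = 1 / (k1 (A^n gamma + K_A^n)) - (T/2)(1 - gamma)

exceeds the sustained rise time ``tau_sus = 1 / (k1 A^n + k2)`` below a
critical K_A (the delay boundary), obtained by solving
``tau_pulsed = tau_sus`` for K_A^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .analytic import mean_pulsed_binding, pulse_end_levels
from .kinetics import HillParameters
from .signal import SquareWaveSignal

__all__ = [
    "RegimeReport",
    "classify_regime",
    "rise_time_sustained",
    "rise_time_pulsed",
    "delay_boundary",
    "delay_factor",
    "graded_clocking",
    "regime_boundaries_vs_KA",
    "fast_boundary_KA",
    "graded_boundary_KA",
]

DEFAULT_THRESHOLD = 10.0
DEFAULT_EPSILON = 0.1

SLOW = "slow_d"
COMPETITIVE = "competitive_e"
FAST = "fast_f"
SUSTAINED = "sustained"


class PulsedRiseTime(NamedTuple):
    """Eq.-of-motion rise time with a validity flag (fast-pulsing formula)."""

    time: float
    valid: bool


@dataclass(frozen=True)
class RegimeReport:
    """Classification of one parameter set under one pulse train."""

    regime: str                      # slow_d / competitive_e / fast_f / sustained
    x: float                         # k2 (1 - gamma) T; nan for sustained
    graded_g: bool
    tau_sus: float                   # h
    tau_pulsed: float | None         # h; fast-pulsing formula, may be invalid
    tau_pulsed_valid: bool
    delay_factor: float | None       # tau_pulsed / tau_sus, small-T limit
    fast_boundary_K_A: float | None  # nM
    delay_boundary_K_A: float | None # nM; None: binding never significantly delayed
    graded_boundary_K_A: float | None  # nM
    threshold: float = DEFAULT_THRESHOLD
    epsilon: float = DEFAULT_EPSILON

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def rise_time_sustained(params: HillParameters, A: float) -> float:
    """Sustained-signal rise time ``1 / (k1 A^n + k2)`` in h.

    The sustained trajectory is a single exponential, so this is exactly
    the time to reach (1 - 1/e) of the asymptote.  Unbounded (inf) when
    A = 0 and k2 = 0.
    """
    rate = params.k1 * A**params.n + params.k2
    return math.inf if rate == 0 else 1.0 / rate


def rise_time_pulsed(
    params: HillParameters, signal: SquareWaveSignal
) -> PulsedRiseTime:
    """Fast-pulsing rise time of the pulse-averaged binding, in h.

    ``1 / (k1 (A^n gamma + K_A^n)) - (T/2)(1 - gamma)``.  The formula is
    derived for regime f; outside it the value can be negative and is
    returned as-is with ``valid=False``.
    """
    g = signal.duty_cycle
    rate = params.k1 * signal.amplitude**params.n * g + params.k2
    value = 1.0 / rate - 0.5 * signal.period * (1.0 - g)
    x = params.k2 * (1.0 - g) * signal.period
    return PulsedRiseTime(time=value, valid=value > 0 and x < 1)


def delay_factor(params: HillParameters, signal: SquareWaveSignal) -> float:
    """Small-period slowdown ``tau_pulsed / tau_sus = (A^n + K_A^n) / (A^n gamma + K_A^n)``.

    Tends to ``1 + A^n / K_A^n`` as gamma -> 0; equals 1 for sustained
    signaling.
    """
    An = signal.amplitude**params.n
    Kn = params.K_d
    return (An + Kn) / (An * signal.duty_cycle + Kn)


def delay_boundary(
    params: HillParameters, signal: SquareWaveSignal
) -> float | None:
    """Largest K_A (nM) for which pulsing significantly delays binding.

    Solving ``tau_pulsed = tau_sus`` for K_A^n gives

        K_A = A { [ ((1-gamma)^2 + 8/(k1 T A^n))^(1/2) - (1+gamma) ] / 2 }^(1/n);

    below this boundary the pulsed rise time exceeds the sustained one.
    Returns None when the braced quantity is non-positive (which happens
    iff k1 T A^n gamma >= 2): no real K_A satisfies the condition and
    binding is never significantly delayed.
    """
    if signal.is_sustained:
        return None
    A, g, T = signal.amplitude, signal.duty_cycle, signal.period
    if A == 0:
        return None
    An = A**params.n
    braced = math.sqrt((1.0 - g) ** 2 + 8.0 / (params.k1 * T * An)) - (1.0 + g)
    if braced <= 0:
        return None
    return A * (0.5 * braced) ** (1.0 / params.n)


def fast_boundary_KA(
    n: float, k1: float, gamma: float, T: float
) -> float | None:
    """K_A at which ``k2 (1 - gamma) T = 1`` (with k2 = k1 K_A^n).

    Marks the slow/fast changeover (regime e) on an affinity axis; None for
    sustained signaling.
    """
    if gamma == 1:
        return None
    return (1.0 / (k1 * (1.0 - gamma) * T)) ** (1.0 / n)


def graded_boundary_KA(
    n: float,
    k1: float,
    A: float,
    gamma: float,
    T: float,
    epsilon: float = DEFAULT_EPSILON,
) -> float | None:
    """Largest K_A in the graded-clocking regime g, or None.

    Operational form of the graded condition with "<<" read as a factor
    ``epsilon``: ``k2 T <= epsilon (1 - k1 A^n gamma T)``, i.e.
    ``K_A^n <= epsilon (1/(k1 T) - gamma A^n)``; the regime exists at all
    only when ``k1 A^n gamma T <= epsilon``.
    """
    if gamma == 1:
        return None
    drive = k1 * A**n * gamma * T
    if drive > epsilon:
        return None
    return (epsilon * (1.0 / (k1 * T) - gamma * A**n)) ** (1.0 / n)


@dataclass(frozen=True)
class GradedClockingResult:
    satisfied: bool
    per_pulse_levels: np.ndarray = field(repr=False)  # P_i(T), i = 1..i_max
    linearity_error: float
    linear_window: int


def graded_clocking(
    params: HillParameters,
    signal: SquareWaveSignal,
    i_max: int = 50,
    epsilon: float = DEFAULT_EPSILON,
) -> GradedClockingResult:
    """Test for graded clocking and measure per-pulse linearity.

    ``satisfied`` requires both ``k2 T <= epsilon (1 - k1 A^n gamma T)``
    and ``k1 A^n gamma T <= epsilon``.  ``per_pulse_levels`` are the exact
    end-of-period levels P_i(T); the linearity error is
    ``max_i |P_i(T) / (i P_1(T)) - 1|`` over the initial linear window
    ``i <= 0.1 P_pulsed / P_1(T)`` (at least i = 1).
    """
    if i_max < 3:
        raise ValueError("i_max must be >= 3")
    A, g, T = signal.amplitude, signal.duty_cycle, signal.period
    drive = params.k1 * A**params.n * g * T
    satisfied = (params.k2 * T <= epsilon * (1.0 - drive)) and (drive <= epsilon)
    levels = pulse_end_levels(params, signal, i_max)
    p1 = levels[0]
    if p1 <= 0:
        return GradedClockingResult(False, levels, 0.0, 1)
    window = int(min(i_max, max(1, math.floor(0.1 * mean_pulsed_binding(params, signal) / p1))))
    i = np.arange(1, window + 1)
    linearity_error = float(np.max(np.abs(levels[:window] / (i * p1) - 1.0)))
    return GradedClockingResult(satisfied, levels, linearity_error, window)


def classify_regime(
    params: HillParameters,
    signal: SquareWaveSignal,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
) -> RegimeReport:
    """Classify the pulsing regime of one parameter set.

    The label depends only on ``x = k2 (1 - gamma) T``: slow_d for
    ``x >= threshold``, fast_f for ``x <= 1/threshold``, competitive_e in
    between.  Sustained signaling (gamma = 1) gets the distinct status
    'sustained' rather than being forced into a pulsing regime.
    """
    if not threshold > 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    A = signal.amplitude
    tau_s = rise_time_sustained(params, A)
    if signal.is_sustained:
        return RegimeReport(
            regime=SUSTAINED, x=math.nan, graded_g=False,
            tau_sus=tau_s, tau_pulsed=tau_s, tau_pulsed_valid=True,
            delay_factor=1.0, fast_boundary_K_A=None,
            delay_boundary_K_A=None, graded_boundary_K_A=None,
            threshold=threshold, epsilon=epsilon,
        )
    x = params.k2 * (1.0 - signal.duty_cycle) * signal.period
    if x >= threshold:
        regime = SLOW
    elif x <= 1.0 / threshold:
        regime = FAST
    else:
        regime = COMPETITIVE
    tau_p = rise_time_pulsed(params, signal)
    graded = graded_clocking(params, signal, epsilon=epsilon).satisfied
    return RegimeReport(
        regime=regime,
        x=x,
        graded_g=graded,
        tau_sus=tau_s,
        tau_pulsed=tau_p.time,
        tau_pulsed_valid=tau_p.valid,
        delay_factor=delay_factor(params, signal),
        fast_boundary_K_A=fast_boundary_KA(
            params.n, params.k1, signal.duty_cycle, signal.period
        ),
        delay_boundary_K_A=delay_boundary(params, signal),
        graded_boundary_K_A=graded_boundary_KA(
            params.n, params.k1, A, signal.duty_cycle, signal.period, epsilon
        ),
        threshold=threshold,
        epsilon=epsilon,
    )


def regime_boundaries_vs_KA(
    n: float,
    k1: float,
    A: float,
    gamma: float,
    T: float,
    K_A_grid,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, dict]:
    """Regime membership along an affinity axis, with boundary markers.

    For every K_A on the (positive, increasing) grid, with ``k2 = k1 K_A^n``,
    the table records the regime label, graded-clocking membership and
    whether the grid point is the last one inside each boundary.  The
    second return value maps boundary names to K_A values (None when the
    boundary does not exist; omitted from markers when outside the grid
    span).  Sustained signaling has no boundaries.
    """
    grid = np.asarray(K_A_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("K_A_grid must be positive and increasing")
    boundaries = {
        "fast": None if gamma == 1 else fast_boundary_KA(n, k1, gamma, T),
        "delay": None,
        "graded": None if gamma == 1 else graded_boundary_KA(n, k1, A, gamma, T, epsilon),
    }
    rows = []
    if gamma < 1:
        sig = SquareWaveSignal(amplitude=A, period=T, duty_cycle=gamma)
        boundaries["delay"] = delay_boundary(
            HillParameters.from_dissociation_constant(n, k1, grid[0]), sig
        )  # independent of K_A
    for K in grid:
        params = HillParameters.from_dissociation_constant(n, k1, K)
        if gamma == 1:
            rows.append((K, params.k2, SUSTAINED, False))
            continue
        rep = classify_regime(params, sig, threshold=threshold, epsilon=epsilon)
        rows.append((K, params.k2, rep.regime, rep.graded_g))
    df = pd.DataFrame(rows, columns=["K_A_nM", "k2_per_h", "regime", "graded"])
    for name in ("fast", "delay", "graded"):
        col = f"is_{name}_boundary"
        df[col] = False
        b = boundaries[name]
        if b is not None and grid[0] <= b <= grid[-1]:
            idx = np.nonzero(grid <= b)[0]
            if idx.size:
                df.loc[idx[-1], col] = True
    return df, boundaries
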