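"""Square-wave signal model.

The forcing signal is a train of rectangular concentration pulses of
amplitude ``A`` (nM), period ``T`` (h) and duty cycle ``gamma``: during the
first fraction ``gamma`` of every period the signal-molecule concentration
is ``A``, for the remainder it is zero.  ``gamma = 1`` is sustained
signaling (the signal is on for all t >= 0).

On-intervals are half-open, ``[(i-1)T, (i-1)T + pulse_on)``: the instant a
pulse starts belongs to the on-state, the instant it ends to the off-state.
This convention matters only on a set of measure zero but keeps the
piecewise analytic solutions single-valued at pulse edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SquareWaveSignal"]


@dataclass(frozen=True)
class SquareWaveSignal:
    """A square-wave concentration signal.

    Parameters
    ----------
    amplitude : float
        Peak signal-molecule concentration ``A`` in nM (>= 0).
    period : float
        Pulsing period ``T`` in h (> 0).
    duty_cycle : float
        Fraction ``gamma`` of each period the signal is on, in (0, 1].
        ``gamma = 0`` (a signal that is never on) is rejected; ``gamma = 1``
        means sustained signaling.
    """

    amplitude: float
    period: float
    duty_cycle: float

    def __post_init__(self) -> None:
        if not self.amplitude >= 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.period > 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError(
                f"duty_cycle must be in (0, 1], got {self.duty_cycle}"
            )

    @property
    def pulse_on(self) -> float:
        """Pulse-on duration ``Delta = gamma * T`` in h."""
        return self.duty_cycle * self.period

    @property
    def is_sustained(self) -> bool:
        return self.duty_cycle == 1

    def concentration(self, t):
        """Signal concentration [S](t) in nM; ``t`` may be a scalar or array.

        Raises ``ValueError`` for negative times (the signal starts at 0).
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("signal is defined for t >= 0 only")
        phase = np.mod(t, self.period)
        out = np.where(phase < self.pulse_on, self.amplitude, 0.0)
        return out if out.ndim else float(out)

    def mean_concentration(self) -> float:
        """Period-averaged concentration ``gamma * A`` in nM."""
        return self.duty_cycle * self.amplitude

    def pulse_phase(self, t):
        """Pulse index and phase for time ``t``.

        Returns ``(i, xi)`` with ``i = floor(t/T) + 1`` the 1-based index of
        the pulse containing ``t`` and ``xi = t - (i - 1)T`` in ``[0, T)``
        the time elapsed since that pulse began.  Period boundaries open a
        new pulse.  Vectorized over ``t``.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("signal is defined for t >= 0 only")
        i = np.floor(t / self.period).astype(int) + 1
        xi = t - (i - 1) * self.period
        if t.ndim:
            return i, xi
        return int(i), float(xi)
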