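"""Scenario grids: binding probability over an affinity axis versus time.

Reproduces the standard presentation of pulsed Hill-type scenarios: a
matrix P(t; K_A) with K_A log-spaced (1-64 nM by default), all other
parameters held fixed, plus the regime boundary affinities (fast, delay,
graded) for overlay.  A registry of 20 panel parameter tuples covers the
reference survey: A in {10, 20, 40} nM crossed with duty cycles
{1, 0.8, 0.3, 0.1} at k1 = 10e-3 nM^-n h^-1, plus A = 40 nM rows at
k1 in {0.1, 1}e-3 (the latter combinations are inferred rather than
explicitly enumerated in the source survey and are flagged as such).
T = 6 h throughout, typical of observed p53 pulsing periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import analytic_binding
from .kinetics import HillParameters, integrate_numeric
from .regimes import (
    DEFAULT_EPSILON,
    DEFAULT_THRESHOLD,
    delay_boundary,
    fast_boundary_KA,
    graded_boundary_KA,
)
from .signal import SquareWaveSignal

__all__ = ["ScenarioGrid", "generate_fig3_grid", "PANEL_REGISTRY"]


@dataclass(frozen=True)
class ScenarioGrid:
    """P(t; K_A) matrix with rows = K_A values, columns = time points."""

    K_A: np.ndarray                 # nM, log-spaced
    times: np.ndarray               # h
    P: np.ndarray                   # shape (len(K_A), len(times)), in [0, 1]
    parameters: dict                # n, k1, A, gamma, T banner
    boundaries: dict                # fast / delay / graded K_A values or None

    def __post_init__(self) -> None:
        if self.P.shape != (len(self.K_A), len(self.times)):
            raise ValueError("P matrix shape must be (|K_A|, |times|)")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("P entries must lie in [0, 1]")

    def to_csv(self, path_or_buf) -> None:
        """Matrix CSV: '#' banner lines, then header K_A_nM,t=...h columns."""
        banner = " ".join(f"{k}={v}" for k, v in self.parameters.items())
        bounds = " ".join(f"{k}_boundary_K_A={v}" for k, v in self.boundaries.items())
        lines = [f"# {banner}", f"# {bounds}"]
        lines.append("K_A_nM," + ",".join(f"{t:.12g}" for t in self.times))
        for K, row in zip(self.K_A, self.P):
            lines.append(f"{K:.12g}," + ",".join(f"{p:.12g}" for p in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    def to_png(self, path, cmap: str = "gray") -> None:  # pragma: no cover
        """Optional cosmetic heatmap; requires matplotlib."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.pcolormesh(self.times, self.K_A, self.P, cmap=cmap, vmin=0, vmax=1)
        ax.set_yscale("log")
        ax.set_xlabel("t (h)")
        ax.set_ylabel("K_A (nM)")
        for name, color in (("fast", "tab:brown"), ("delay", "grey"), ("graded", "magenta")):
            b = self.boundaries.get(name)
            if b is not None and self.K_A[0] <= b <= self.K_A[-1]:
                ax.axhline(b, color=color, ls="--", lw=1, label=name)
        ax.legend(loc="upper right", fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def generate_fig3_grid(
    n: float,
    k1: float,
    A: float,
    gamma: float,
    T: float = 6.0,
    K_A_range: tuple[float, float] = (1.0, 64.0),
    n_KA: int = 64,
    t_end: float | None = None,
    points_per_period: int = 200,
    method: str = "analytic",
    epsilon: float = DEFAULT_EPSILON,
) -> ScenarioGrid:
    """Fill a P(t; K_A) scenario panel.

    Rows are ``n_KA`` log-spaced affinities over ``K_A_range``; columns a
    uniform time grid of ``points_per_period`` samples per period out to
    ``t_end`` (default 4 T).  Rows are evaluated with the closed-form
    trajectory (``method="analytic"``) or the segment-exact integrator
    (``method="numeric"``).
    """
    if t_end is None:
        t_end = 4.0 * T
    K_A = np.logspace(np.log10(K_A_range[0]), np.log10(K_A_range[1]), n_KA)
    n_t = max(2, int(round(points_per_period * t_end / T)) + 1)
    times = np.linspace(0.0, t_end, n_t)
    sig = SquareWaveSignal(amplitude=A, period=T, duty_cycle=gamma)
    P = np.empty((n_KA, n_t))
    for j, K in enumerate(K_A):
        params = HillParameters.from_dissociation_constant(n, k1, K)
        if method == "analytic":
            P[j] = analytic_binding(params, sig, times)
        elif method == "numeric":
            traj = integrate_numeric(params, sig, t_end, dt_out=times[1] - times[0])
            P[j] = np.interp(times, traj.times, traj.probabilities)
        else:
            raise ValueError(f"unknown method {method!r}")
    if gamma < 1:
        boundaries = {
            "fast": fast_boundary_KA(n, k1, gamma, T),
            "delay": delay_boundary(
                HillParameters.from_dissociation_constant(n, k1, K_A[0]), sig
            ),
            "graded": graded_boundary_KA(n, k1, A, gamma, T, epsilon),
        }
    else:
        boundaries = {"fast": None, "delay": None, "graded": None}
    return ScenarioGrid(
        K_A=K_A,
        times=times,
        P=np.clip(P, 0.0, 1.0),
        parameters={"n": n, "k1": k1, "A": A, "gamma": gamma, "T": T},
        boundaries=boundaries,
    )


def _build_registry() -> tuple[dict, ...]:
    """The 20 reference panels: (A, k1) rows crossed with duty cycles."""
    duty_cycles = (1.0, 0.8, 0.3, 0.1)
    rows = [
        {"A": 10.0, "k1": 10e-3, "inferred": False},
        {"A": 20.0, "k1": 10e-3, "inferred": False},
        {"A": 40.0, "k1": 10e-3, "inferred": False},
        {"A": 40.0, "k1": 1e-3, "inferred": True},
        {"A": 40.0, "k1": 0.1e-3, "inferred": True},
    ]
    return tuple(
        {"n": 2, "A": row["A"], "k1": row["k1"], "gamma": g, "T": 6.0,
         "inferred": row["inferred"]}
        for row in rows
        for g in duty_cycles
    )


#: Parameter tuples of the 20 reference scenario panels (n = 2, T = 6 h).
PANEL_REGISTRY = _build_registry()
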