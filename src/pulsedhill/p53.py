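"""Dimerization-coupled promoter binding: the p53 application.

p53 monomers equilibrate rapidly into dimers,

    2 p53 <-> p53_2,          K_Ad = [p53]^2 / [p53_2]  (nM),

and two dimers bind a gene promoter cooperatively,

    2 p53_2 + DNA <-> DNA.4p53,   K_AR^2 = k2R / k1R    (nM^2),

so the asymptotic promoter occupancy under a sustained p53 level is

    P_sus = [p53_2]^2 / (K_AR^2 + [p53_2]^2).

Dimerization is treated as instantaneously equilibrated (quasi-steady
state), and p53 sequestered on the DNA is neglected in the mass balance
[p53]_total = [p53] + 2 [p53_2].  Eliminating the monomer yields a closed
form for the dimer concentration, and in the two limits the scheme
collapses onto a plain Hill model:

    strong dimerization (K_Ad << 4 [p53]_total):
        n = 2, S = p53_2, K_A = K_AR, A = [p53]_total / 2;
    weak dimerization (K_Ad >> 4 [p53]_total):
        n = 4, S = p53 monomer, A = [p53]_total, K_A^4 = K_AR^2 K_Ad^2.

The strong-limit mapping lets every square-wave result in this package be
applied to promoter panels differing only in their affinity K_AR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .kinetics import HillParameters
from .regimes import (
    DEFAULT_EPSILON,
    DEFAULT_THRESHOLD,
    RegimeReport,
    classify_regime,
)
from .signal import SquareWaveSignal

__all__ = [
    "DimerizationSystem",
    "dimer_concentration",
    "sustained_binding_dimer",
    "effective_hill_map",
    "limiting_hill_maps",
    "StrongDimerizationError",
    "promoter_scenario",
    "promoter_panel",
    "DEFAULT_K1R",
]

# Default dimer-DNA association rate constant (nM^-2 h^-1) when only the
# promoter affinity K_AR is known; matches the central association-rate row
# of the parameter grids used throughout the package (k1 = 10e-3 nM^-2 h^-1,
# motivated by near-diffusion-limited association).
DEFAULT_K1R = 0.01

# Default reading of "K_Ad << 4 [p53]_total" for accepting the strong-
# dimerization Hill mapping: K_Ad at most a tenth of 4 [p53]_total.
STRONG_DIMERIZATION_FACTOR = 10.0


def dimer_concentration(K_Ad: float, p53_total: float) -> float:
    """Equilibrium dimer concentration [p53_2] in nM.

    Root of the dimerization equilibrium combined with the mass balance,

        8 [p53_2] = 4 [p53]_total + K_Ad - (K_Ad^2 + 8 K_Ad [p53]_total)^(1/2),

    evaluated in the cancellation-free conjugate form

        [p53_2] = 2 [p53]_total^2 / (4 [p53]_total + K_Ad + sqrt(...)).

    K_Ad -> 0 gives full dimerization, [p53]_total / 2.
    """
    if not K_Ad >= 0:
        raise ValueError(f"K_Ad must be >= 0, got {K_Ad}")
    if not p53_total >= 0:
        raise ValueError(f"p53_total must be >= 0, got {p53_total}")
    if p53_total == 0:
        return 0.0
    root = math.sqrt(K_Ad * K_Ad + 8.0 * K_Ad * p53_total)
    return 2.0 * p53_total**2 / (4.0 * p53_total + K_Ad + root)


@dataclass(frozen=True)
class DimerizationSystem:
    """Dimerizing transcription factor binding a promoter as a dimer pair.

    ``K_Ad`` (nM) is the dimerization dissociation constant, ``K_AR`` (nM)
    the promoter-binding dissociation constant (``K_AR^2 = k2R / k1R``),
    and ``p53_total`` (nM) the conserved total monomer-equivalent
    concentration.  Rate constants are optional; when both members of a
    pair are supplied they must be consistent with the corresponding
    dissociation constant.
    """

    K_Ad: float
    K_AR: float
    p53_total: float
    k1d: float | None = None   # nM^-1 h^-1
    k2d: float | None = None   # h^-1
    k1R: float | None = None   # nM^-2 h^-1
    k2R: float | None = None   # h^-1

    def __post_init__(self) -> None:
        if not self.K_Ad >= 0:
            raise ValueError(f"K_Ad must be >= 0, got {self.K_Ad}")
        if not self.K_AR > 0:
            raise ValueError(f"K_AR must be > 0, got {self.K_AR}")
        if not self.p53_total >= 0:
            raise ValueError(f"p53_total must be >= 0, got {self.p53_total}")
        if self.k1d is not None and self.k2d is not None:
            if not math.isclose(self.k2d / self.k1d, self.K_Ad, rel_tol=1e-9):
                raise ValueError("k2d / k1d is inconsistent with K_Ad")
        if self.k1R is not None and self.k2R is not None:
            if not math.isclose(self.k2R / self.k1R, self.K_AR**2, rel_tol=1e-9):
                raise ValueError("k2R / k1R is inconsistent with K_AR^2")

    @property
    def p53_dimer(self) -> float:
        """Equilibrium dimer concentration (nM)."""
        return dimer_concentration(self.K_Ad, self.p53_total)

    @property
    def p53_monomer(self) -> float:
        """Equilibrium monomer concentration, from the mass balance (nM)."""
        return self.p53_total - 2.0 * self.p53_dimer


def sustained_binding_dimer(sys: DimerizationSystem) -> float:
    """Asymptotic promoter occupancy at sustained total p53.

    Computes the equilibrium dimer level, then
    ``P_sus = [p53_2]^2 / (K_AR^2 + [p53_2]^2)``.
    """
    d = sys.p53_dimer
    if d == 0:
        return 0.0
    return d * d / (sys.K_AR**2 + d * d)


def limiting_hill_maps(sys: DimerizationSystem, k1R: float | None = None) -> dict:
    """Both limiting plain-Hill mappings of the dimerization scheme.

    Returns ``{"strong": (HillParameters, A), "weak": (HillParameters, A)}``.
    The weak-limit rate constant reuses the supplied association rate
    numerically (only the equilibrium constant K_A^4 = K_AR^2 K_Ad^2 is
    fixed by the scheme; the kinetic prefactor is a convention).
    """
    k1 = k1R if k1R is not None else (sys.k1R if sys.k1R is not None else DEFAULT_K1R)
    strong = (
        HillParameters.from_dissociation_constant(2, k1, sys.K_AR),
        sys.p53_total / 2.0,
    )
    weak_KA = math.sqrt(sys.K_AR * sys.K_Ad) if sys.K_Ad > 0 else 0.0
    weak = (
        HillParameters.from_dissociation_constant(4, k1, weak_KA),
        sys.p53_total,
    )
    return {"strong": strong, "weak": weak}


class StrongDimerizationError(ValueError):
    """Raised when the strong-dimerization Hill mapping is not applicable.

    Carries both limiting mappings in ``limiting_maps`` so callers can pick
    the appropriate one explicitly.
    """

    def __init__(self, message: str, limiting_maps: dict):
        super().__init__(message)
        self.limiting_maps = limiting_maps


def effective_hill_map(
    sys: DimerizationSystem,
    k1R: float | None = None,
    strong_factor: float = STRONG_DIMERIZATION_FACTOR,
) -> tuple[HillParameters, float]:
    """Strong-dimerization plain-Hill mapping ``(HillParameters, amplitude)``.

    Under strong dimerization (accepted when
    ``K_Ad <= 4 p53_total / strong_factor``) the scheme is the n = 2 Hill
    model with S = p53_2, K_A = K_AR and peak amplitude
    ``A = [p53]_total / 2``, so every square-wave result applies unchanged.
    Outside that regime the mapping is refused with both limiting mappings
    attached to the raised :class:`StrongDimerizationError`.
    """
    maps = limiting_hill_maps(sys, k1R=k1R)
    if sys.p53_total > 0 and sys.K_Ad <= 4.0 * sys.p53_total / strong_factor:
        return maps["strong"]
    raise StrongDimerizationError(
        f"K_Ad = {sys.K_Ad} nM is not << 4 [p53]_total = {4 * sys.p53_total} nM; "
        "the strong-dimerization n=2 mapping does not apply "
        "(the weak limit maps onto n=4 with A = [p53]_total and "
        "K_A^4 = K_AR^2 K_Ad^2)",
        limiting_maps=maps,
    )


def promoter_scenario(
    promoter_K_AR: float,
    p53_total: float,
    signal: SquareWaveSignal,
    K_Ad: float = 0.0,
    k1R: float = DEFAULT_K1R,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
) -> RegimeReport:
    """Classify the pulsing regime of a single promoter.

    ``signal`` describes the pulsing of *total* p53 with amplitude equal to
    the peak total concentration; the dimer-level amplitude of the
    effective n = 2 Hill model is half of it.  Strong dimerization is
    assumed (the usual assumption of fast dimer equilibration), so ``K_Ad``
    defaults to 0.
    """
    sys = DimerizationSystem(K_Ad=K_Ad, K_AR=promoter_K_AR, p53_total=p53_total)
    params, amplitude = effective_hill_map(sys, k1R=k1R)
    eff_signal = SquareWaveSignal(
        amplitude=amplitude, period=signal.period, duty_cycle=signal.duty_cycle
    )
    return classify_regime(params, eff_signal, threshold=threshold, epsilon=epsilon)


def promoter_panel(
    promoters_csv,
    p53_total: float,
    signal: SquareWaveSignal,
    K_Ad: float = 0.0,
    k1R: float = DEFAULT_K1R,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, RegimeReport]:
    """Classify a panel of promoters from a two-column CSV.

    The CSV has columns ``promoter_name, K_AR_nM``; promoters differ only
    in their binding affinity.
    """
    df = pd.read_csv(promoters_csv)
    expected = ["promoter_name", "K_AR_nM"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"promoter CSV must have columns {expected}, got {list(df.columns)}")
    return {
        str(row.promoter_name): promoter_scenario(
            float(row.K_AR_nM), p53_total, signal,
            K_Ad=K_Ad, k1R=k1R, threshold=threshold, epsilon=epsilon,
        )
        for row in df.itertuples(index=False)
    }
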