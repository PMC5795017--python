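import numpy as np
import pytest

from pulsedhill import HillParameters, SquareWaveSignal


@pytest.fixture
def default_params() -> HillParameters:
    """n = 2, k1 = 0.01 nM^-2 h^-1, K_A = 8 nM."""
    return HillParameters.from_dissociation_constant(2, 0.01, 8.0)


@pytest.fixture
def default_signal() -> SquareWaveSignal:
    """A = 10 nM, T = 6 h, gamma = 0.3 (a typical p53-like pulse train)."""
    return SquareWaveSignal(amplitude=10.0, period=6.0, duty_cycle=0.3)


def random_draws(rng: np.random.Generator, n_draws: int, gamma_range=(0.05, 0.95)):
    """Random Hill/signal parameter draws spanning the survey ranges.

    n in {2, 4}; k1 log-uniform over [1e-4, 1e-2] nM^-n h^-1; K_A
    log-uniform over [1, 64] nM; A log-uniform over [5, 80] nM; gamma
    uniform.  With T = 6 h this spans k2 T from ~1e-3 to ~1e5.
    """
    out = []
    for _ in range(n_draws):
        n = int(rng.choice([2, 4]))
        k1 = 10.0 ** rng.uniform(-4, -2)
        K_A = 10.0 ** rng.uniform(0, np.log10(64))
        A = 10.0 ** rng.uniform(np.log10(5), np.log10(80))
        gamma = rng.uniform(*gamma_range)
        out.append(
            (
                HillParameters.from_dissociation_constant(n, k1, K_A),
                SquareWaveSignal(amplitude=A, period=6.0, duty_cycle=gamma),
            )
        )
    return out
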