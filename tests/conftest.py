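import numpy as np
import pytest

from aiqp import simulate_qrs
from aiqp.rbfnn import design_matrix


@pytest.fixture(scope="session")
def qrs():
    """Default synthetic normal QRS window (p = 200 at 2 kHz)."""
    return simulate_qrs()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _greedy_refit_oracle(y, sigma, M, tie_tol=1e-12):
    """Exhaustive greedy selection oracle, independent of the OLS recursion.

    At each step, refit the full least squares problem for every remaining
    candidate center and keep the one with the lowest SSE (largest SSE
    decrease); ties within ``tie_tol`` of the signal energy resolve to the
    smallest center index by scanning candidates in increasing order.
    """
    y = np.asarray(y, dtype=float)
    p = y.size
    yty = float(y @ y)
    selected: list = []
    remaining = list(range(1, p + 1))
    for _ in range(M):
        best_sse, best_c = None, None
        for c in remaining:
            phi = design_matrix(p, selected + [c], sigma)
            w, *_ = np.linalg.lstsq(phi, y, rcond=None)
            sse = float(np.sum((y - phi @ w) ** 2))
            if best_sse is None or sse < best_sse - tie_tol * yty:
                best_sse, best_c = sse, c
        selected.append(best_c)
        remaining.remove(best_c)
    return selected


@pytest.fixture(scope="session")
def greedy_refit_oracle():
    """The exhaustive refit-per-candidate greedy selection oracle."""
    return _greedy_refit_oracle
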