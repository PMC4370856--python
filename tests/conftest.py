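import itertools

import numpy as np
import pytest

import landfolio as lf


@pytest.fixture(scope="session")
def table():
    return lf.load_series_table()


@pytest.fixture(scope="session")
def default_specs():
    return lf.load_default_specs()


@pytest.fixture(scope="session")
def ref_stats():
    return lf.load_reference_stats()


@pytest.fixture(scope="session")
def ref_corr():
    return lf.load_reference_correlations()


def simplex_grid(n: int, step: float = 0.01):
    """All weight vectors on the n-simplex lattice with the given step."""
    m = round(1.0 / step)
    for cuts in itertools.combinations_with_replacement(range(m + 1), n - 1):
        parts = np.diff((0, *cuts, m))
        yield parts / m


def grid_search(means, cov, step=0.01, floor=None, cap=None):
    """Brute-force oracle: best simplex-lattice portfolio.

    Returns (weights, return, sd) minimizing variance (or maximizing return
    when a risk cap is given) under the same constraints as the QP.
    """
    means = np.asarray(means, float)
    best = None
    for w in simplex_grid(len(means), step):
        r = float(w @ means)
        v = float(w @ cov @ w)
        if floor is not None and r < floor - 1e-12:
            continue
        if cap is not None:
            if np.sqrt(v) > cap + 1e-12:
                continue
            key = (-r, v)
        else:
            key = (v, -r)
        if best is None or key < best[0]:
            best = (key, w, r, np.sqrt(v))
    if best is None:
        return None
    return best[1], best[2], best[3]
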