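"""Numba kernels for the beta-Markov read-depth chain.

The chain state is the emitted integer read depth: at each step the previous
depth is scaled back to [0, 1] and fed into the conditional mean, so the
transition matrix over integer depths is exactly the object the doublet
statistics (e_xy = p_x * p_xy) are defined on.  A pure-numpy implementation of
a 10^7-site chain takes minutes; the JIT version takes about a second.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_CONDITIONAL_MEAN = 0
MODEL_COPY = 1

_EPS = 1e-9  # clamp for conditional means that touch 0 or 1 by floating error


@njit(cache=False)
def beta_markov_latent(
    xbar: float,
    p: float,
    ap: float,
    dmin: float,
    dmax: float,
    n: int,
    seed: int,
    model: int,
) -> np.ndarray:
    """Simulate n latent scaled depths x_1..x_n.

    model 0 (conditional-mean): x_j ~ beta with mean p*x'_{j-1} + (1-p)*xbar
    and concentration ap, where x'_{j-1} is the scaled rounded depth of the
    previous site.  model 1 (copy): with probability p the previous x is
    copied, otherwise x_j ~ beta(xbar*ap, (1-xbar)*ap).
    """
    np.random.seed(seed)
    x = np.empty(n)
    span = dmax - dmin
    xj = np.random.beta(xbar * ap, (1.0 - xbar) * ap)
    x[0] = xj
    for j in range(1, n):
        if model == MODEL_COPY:
            if np.random.random() >= p:
                xj = np.random.beta(xbar * ap, (1.0 - xbar) * ap)
        else:
            dprev = np.floor(dmin + xj * span + 0.5)
            xprev = (dprev - dmin) / span
            m = p * xprev + (1.0 - p) * xbar
            if m < _EPS:
                m = _EPS
            elif m > 1.0 - _EPS:
                m = 1.0 - _EPS
            xj = np.random.beta(m * ap, (1.0 - m) * ap)
        x[j] = xj
    return x
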