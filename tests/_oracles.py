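"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the ODE oracle solves
the forced linear equation by integrating-factor quadrature (adaptive
Gauss-Kronrod) instead of time stepping.
"""

import math

import numpy as np
from scipy.integrate import quad


def integrating_factor_solution(params, reporter, times_h, c0=0.0):
    """c(t) = c0 e^(-delta t) + integral_0^t e^(-delta (t-s)) F(s) ds."""
    delta = params.delta(reporter)

    def forcing(s):
        return params.k1 * math.exp(math.sin(2 * math.pi * s / params.period_h + params.phase_rad))

    out = []
    for t in np.asarray(times_h, dtype=float):
        integral, _ = quad(
            lambda s: math.exp(-delta * (t - s)) * forcing(s),
            0.0,
            t,
            limit=500,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        out.append(c0 * math.exp(-delta * t) + integral)
    return np.array(out)
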