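"""Independent numeric oracles used by the tests.

These deliberately avoid the closed forms implemented in the package: the
time-integrated activity is obtained by adaptive quadrature of the evaluated
curve, and the Lea-Catcheside factor from its defining double integral over
the (normalised) dose-rate history,

    G = 2 ∫₀^∞ A(t) ∫₀^t A(w) e^{−µ(t−w)} dw dt  /  (∫₀^∞ A(t) dt)².
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from tacdose.tac_models import ModelId, TacParams, evaluate


def tia_quadrature(model: ModelId, params: TacParams) -> float:
    """TIA in MBq·h by adaptive quadrature of the TAC over [0, ∞)."""
    value, _ = quad(lambda t: evaluate(model, params, t), 0.0, np.inf,
                    epsabs=0.0, epsrel=1e-10, limit=200)
    return value


def _panel_nodes(edges: np.ndarray, order: int = 64):
    """Gauss–Legendre nodes/weights on consecutive panels [e0,e1],[e1,e2],..."""
    x, w = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        h = 0.5 * (hi - lo)
        nodes.append(lo + h * (x + 1.0))
        weights.append(h * w)
    return np.concatenate(nodes), np.concatenate(weights)


def lea_catcheside_quadrature(a: tuple[float, ...], lam: tuple[float, ...],
                              mu: float) -> float:
    """G from its double-integral definition for A(t) = Σ aᵢ exp(−λᵢ t).

    The inner repair-kernel integral is evaluated on the lag substitution
    u = t − w with composite Gauss–Legendre panels resolving the e^{−µu}
    boundary layer; the outer integral uses adaptive quadrature.
    """
    a = np.asarray(a, dtype=float)
    lam = np.asarray(lam, dtype=float)

    def activity(t):
        return np.sum(a * np.exp(-lam * t[..., None]), axis=-1)

    # outer nodes on composite panels spanning all decay scales: the
    # integrand is smooth, rises from 0 and decays like exp(-2*min(lam)*t)
    rate_fast = float(np.max(lam)) + mu
    t_max = 40.0 / (2.0 * float(np.min(lam)))
    t_edges = np.concatenate(([0.0], np.geomspace(0.005 / rate_fast, t_max, 28)))
    t_nodes, t_weights = _panel_nodes(t_edges)

    # inner integral ∫₀^t A(t−u) e^{−µu} du on the lag u = t − w, with panels
    # resolving the e^{−µu} kernel, clipped to [0, t] per outer node
    x, w = np.polynomial.legendre.leggauss(64)
    base_edges = np.array([0.0, 1.0 / mu, 5.0 / mu, 15.0 / mu, 45.0 / mu])
    clipped = np.minimum(base_edges[None, :], t_nodes[:, None])   # (n_t, 5)
    lo, hi = clipped[:, :-1], clipped[:, 1:]                      # (n_t, 4)
    half = 0.5 * (hi - lo)
    u = lo[:, :, None] + half[:, :, None] * (x[None, None, :] + 1.0)  # (n_t,4,64)
    uw = half[:, :, None] * w[None, None, :]
    inner = np.sum(uw * activity(t_nodes[:, None, None] - u) * np.exp(-mu * u),
                   axis=(1, 2))

    num = float(np.sum(t_weights * activity(t_nodes) * inner))
    den, _ = quad(lambda t: float(activity(np.asarray(t))), 0.0, np.inf,
                  epsabs=0.0, epsrel=1e-12, limit=200)
    return 2.0 * num / den ** 2
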