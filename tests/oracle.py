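"""Independent brute-force transliteration of the scoring formulas.

The normal CDF is evaluated by Gaussian quadrature of the density and
its quantile by bisection root-finding on that CDF — deliberately
avoiding the distribution objects the implementation uses, so the two
routes are independent.
"""

import math

from scipy.integrate import quad
from scipy.optimize import brentq


def _pdf(t: float) -> float:
    return math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)


def phi(x: float) -> float:
    """Standard normal CDF by quadrature from 0."""
    val, _ = quad(_pdf, 0.0, x, epsabs=1e-14, epsrel=1e-12)
    return 0.5 + val


def phi_inv(q: float) -> float:
    """Standard normal quantile by root finding on the quadrature CDF."""
    return brentq(lambda x: phi(x) - q, -40.0, 40.0, xtol=1e-13)


def tail_transform(d: float, clamp_eps: float = 1e-15) -> float:
    q = 1.0 - 2.0 * (1.0 - phi(d))
    q = min(max(q, clamp_eps), 1.0 - clamp_eps)
    return phi_inv(q)


def node_score(p: float, log2fc: float, clamp_eps: float = 1e-15) -> float:
    d = (-math.log10(max(p, 1e-300))) * abs(log2fc)
    return tail_transform(d, clamp_eps)


def fisher_z(r: float) -> float:
    r = min(max(r, -1 + 1e-7), 1 - 1e-7)
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def edge_xi(r1: float, p1: float, n1: int, r2: float, p2: float, n2: int) -> float:
    num = fisher_z(r2) * (-math.log10(max(p2, 1e-300))) - fisher_z(r1) * (
        -math.log10(max(p1, 1e-300))
    )
    return num / math.sqrt(1.0 / (n2 - 3) + 1.0 / (n1 - 3))


def edge_score(r1, p1, n1, r2, p2, n2, clamp_eps: float = 1e-15) -> float:
    return tail_transform(abs(edge_xi(r1, p1, n1, r2, p2, n2)), clamp_eps)


def triplet_score(node_scores, edge_scores, omega: float = 0.5) -> float:
    return omega * sum(node_scores) / 3.0 + (1 - omega) * sum(edge_scores) / 3.0
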