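"""Numerical solution of the bonded-layer flat-punch indentation problem.

A rigid, flat-ended cylindrical indenter of radius ``a`` pressed into an
elastic layer of thickness ``h`` bonded to a rigid substrate is stiffer
than the same punch on an elastic half-space.  The classical treatment
reduces the mixed boundary-value problem, via Hankel transforms and an
Abel inversion, to a Fredholm integral equation of the second kind for
an auxiliary density ``chi(x)`` on [0, 1].  The stiffness amplification
factor

    kappa(a/h, nu) = F_layer / F_halfspace,   F_halfspace = 2 a E w / (1 - nu^2)

is obtained from the integral of the solved density.  ``kappa -> 1`` as
``a/h -> 0`` and grows monotonically with ``a/h``; for an incompressible
layer (nu = 0.5) the growth is fastest because the bonded substrate
suppresses the volumetric escape route.

This module is the source of the interpolation table bundled with the
package (``data/hayes_kappa.csv``, regenerated by
``scripts/build_hayes_table.py``); :func:`cartispec.biomech.hayes_kappa`
interpolates that table at run time and unit tests cross-check the
interpolant against :func:`kappa_exact`.
"""

from __future__ import annotations

import numpy as np


def _layer_response(y: np.ndarray, nu: float) -> np.ndarray:
    """Dimensionless surface-compliance function N(y) of a bonded layer.

    ``y = xi * h`` is the Hankel variable scaled by the layer thickness and
    ``kappa_e = 3 - 4 nu`` is the Kolosov constant.  N -> 1 recovers the
    half-space; N -> 0 as y -> 0 expresses the rigid backing.  The small-y
    expansion reproduces the oedometric (confined-compression) thin-layer
    compliance for nu < 0.5 and the cubic bending-like law for nu = 0.5.
    """
    y = np.asarray(y, dtype=float)
    ke = 3.0 - 4.0 * nu
    # sinh/cosh overflow past ~350; N is 1 to machine precision long before.
    ys = np.minimum(y, 200.0)
    num = 2.0 * ke * np.sinh(2.0 * ys) - 4.0 * ys
    den = 2.0 * ke * np.cosh(2.0 * ys) + 1.0 + ke * ke + 4.0 * ys * ys
    return num / den


def kappa_exact(
    a_over_h: float,
    nu: float,
    *,
    n_nodes: int = 64,
    y_max: float = 40.0,
    n_y: int = 800,
) -> float:
    """Solve the Fredholm equation and return kappa(a/h, nu).

    Nystrom discretisation with Gauss-Legendre nodes on [0, 1] for the
    density and on [0, y_max] for the kernel's spectral integral (the
    integrand decays like exp(-2y), so y_max = 40 is far beyond machine
    precision).
    """
    if a_over_h < 0:
        raise ValueError("a/h must be non-negative")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5]")
    if a_over_h == 0.0:
        return 1.0

    alpha = float(a_over_h)
    x, wx = np.polynomial.legendre.leggauss(n_nodes)
    x = 0.5 * (x + 1.0)
    wx = 0.5 * wx
    y, wy = np.polynomial.legendre.leggauss(n_y)
    y = 0.5 * y_max * (y + 1.0)
    wy = 0.5 * y_max * wy

    dN = _layer_response(y, nu) - 1.0          # -> 0 exponentially
    C = np.cos(alpha * np.outer(x, y))          # (n_nodes, n_y)
    # K[i, j] = int_0^inf dN(y) cos(alpha x_i y) cos(alpha x_j y) dy
    K = (C * (dN * wy)) @ C.T
    A = np.eye(n_nodes) + (2.0 / np.pi) * alpha * K * wx[None, :]
    chi = np.linalg.solve(A, np.ones(n_nodes))
    # right-hand side normalised to 1, so kappa is the mean of chi.
    return float(np.sum(wx * chi))


def build_table(
    a_over_h_grid: np.ndarray | None = None,
    nu_grid: np.ndarray | None = None,
) -> "np.ndarray":
    """Tabulate kappa on a (a/h, nu) grid; returns rows (a/h, nu, kappa)."""
    if a_over_h_grid is None:
        a_over_h_grid = np.round(np.arange(0.0, 2.0 + 1e-9, 0.025), 4)
    if nu_grid is None:
        nu_grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.05), 3)
    rows = []
    for nu in nu_grid:
        for aoh in a_over_h_grid:
            rows.append((float(aoh), float(nu), kappa_exact(float(aoh), float(nu))))
    return np.array(rows)
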