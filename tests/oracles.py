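"""Independent brute-force oracles used by the test suite.

These implementations deliberately take different computational routes
from the package (series expansions, dense quadrature, constrained
numerical optimization, exhaustive enumeration, permutation) so that
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, special, stats

MU0_OVER_4PI = 1e-7


# ---------------------------------------------------------------------------
# forward-model oracle: Biot-Savart primary field + Geselowitz surface
# integral of the volume currents, with the surface potential from the
# classic Legendre series for a dipole in a homogeneous conducting sphere.


def _surface_potential_times_sigma(
    surf_points: np.ndarray, r0: np.ndarray, q: np.ndarray,
    sphere_radius: float, n_terms: int = 80,
) -> np.ndarray:
    """sigma * V on the sphere surface (the conductivity cancels later).

    Dipole frame: z' along r0; the tangential moment component defines x'.
    V(gamma, phi) = (1/4pi) sum_n (2n+1)/n * b^(n-1)/R^(n+1)
                    * [n q_r P_n(cos g) + q_t cos(phi) P_n^1(cos g)]
    """
    b = np.linalg.norm(r0)
    big_r = sphere_radius
    if b < 1e-12:
        zhat = np.array([0.0, 0.0, 1.0])
        q_r, q_t = 0.0, np.linalg.norm(q)
        xhat = q / q_t if q_t > 0 else np.array([1.0, 0.0, 0.0])
    else:
        zhat = r0 / b
        q_r = q @ zhat
        q_tan = q - q_r * zhat
        q_t = np.linalg.norm(q_tan)
        xhat = q_tan / q_t if q_t > 1e-300 else _any_perp(zhat)
    yhat = np.cross(zhat, xhat)

    cosg = np.clip(surf_points @ zhat / big_r, -1.0, 1.0)
    phi = np.arctan2(surf_points @ yhat, surf_points @ xhat)
    v = np.zeros(len(surf_points))
    for n in range(1, n_terms + 1):
        pn = special.eval_legendre(n, cosg)
        pn1 = special.lpmv(1, n, cosg)
        radial = n * q_r * pn
        tangential = -q_t * np.cos(phi) * pn1  # lpmv includes (-1)^m
        v += (2 * n + 1) / n * b ** (n - 1) / big_r ** (n + 1) * (radial + tangential)
    return v / (4 * np.pi)


def _any_perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def dipole_field_oracle(
    sensor_positions: np.ndarray,
    r0: np.ndarray,
    q: np.ndarray,
    sphere_radius: float = 0.09,
    n_surface: int = 120_000,
    n_terms: int = 80,
) -> np.ndarray:
    """Field of a dipole in a conducting sphere by dense surface quadrature.

    B = B_biot_savart(primary)
        - mu0/4pi * sigma * surface_integral( V n' x (r - r') / |r - r'|^3 )
    """
    r = np.atleast_2d(sensor_positions)
    # primary (Biot-Savart of the current dipole)
    d = r - r0
    dn = np.linalg.norm(d, axis=1)
    b_prim = MU0_OVER_4PI * np.cross(np.broadcast_to(q, d.shape), d) / dn[:, None] ** 3

    surf = _fibonacci_sphere(n_surface) * sphere_radius
    normals = surf / sphere_radius
    weights = 4 * np.pi * sphere_radius**2 / n_surface
    sigma_v = _surface_potential_times_sigma(surf, np.asarray(r0, float),
                                             np.asarray(q, float),
                                             sphere_radius, n_terms)
    b_vol = np.empty_like(b_prim)
    for i, ri in enumerate(r):
        dd = ri - surf
        ddn = np.linalg.norm(dd, axis=1)
        integrand = np.cross(normals, dd) / ddn[:, None] ** 3
        b_vol[i] = -MU0_OVER_4PI * weights * (sigma_v[:, None] * integrand).sum(axis=0)
    return b_prim + b_vol


# ---------------------------------------------------------------------------
# LCMV oracle: numerically minimize w^T C w subject to w^T l = 1.


def lcmv_weight_oracle(c: np.ndarray, l: np.ndarray) -> np.ndarray:
    n = len(l)

    def objective(w):
        return w @ c @ w

    def grad(w):
        return 2 * c @ w

    cons = {"type": "eq", "fun": lambda w: w @ l - 1.0, "jac": lambda w: l}
    w0 = l / (l @ l)
    res = optimize.minimize(objective, w0, jac=grad, constraints=[cons],
                            method="SLSQP", options={"maxiter": 500, "ftol": 1e-16})
    if not res.success:
        raise RuntimeError(f"oracle QP failed: {res.message}")
    return res.x


# ---------------------------------------------------------------------------
# exact signed-rank distribution by exhaustive sign enumeration.


def signrank_enumeration_p(diffs: np.ndarray, alternative: str = "greater") -> float:
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.empty(2**n)
    for i, signs in enumerate(itertools.product([0, 1], repeat=n)):
        ws[i] = ranks[np.array(signs, dtype=bool)].sum()
    if alternative == "greater":
        return float((ws >= w_obs - 1e-12).mean())
    if alternative == "less":
        return float((ws <= w_obs + 1e-12).mean())
    p = 2 * min((ws >= w_obs - 1e-12).mean(), (ws <= w_obs + 1e-12).mean())
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# Kruskal-Wallis permutation null.


def kruskal_permutation_p(groups, n_perm: int = 100_000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    groups = [np.asarray(g, float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = stats.kruskal(*groups).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if stats.kruskal(*parts).statistic >= h_obs - 1e-12:
            count += 1
    return count / n_perm
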