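"""Level-symmetric discrete-ordinates (S_N) angular quadrature sets.

An S_N set has N(N+2) unit directions closed under sign flips of every axis
(octant symmetry).  Weights are normalized to sum to 1 over the full sphere,
so the scalar fluence is the bare weighted sum of angular fluences and no 4*pi
factors appear in the multigroup scattering source.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["QuadratureSet", "build_level_symmetric", "angular_moment"]

# First level cosine mu_1 of the classic LQ_N construction, N = 2..16.
_MU1 = {
    2: 0.5773503,
    4: 0.3500212,
    6: 0.2666355,
    8: 0.2182179,
    10: 0.1893213,
    12: 0.1672126,
    14: 0.1519859,
    16: 0.1389568,
}

# Tabulated per-octant point weights by point class for the low orders; the
# class of an octant point is the sorted level-index triple (i, j, k),
# i + j + k = N/2 + 2.  Octant weights sum to 1 (divide by 8 for the sphere).
_POINT_WEIGHTS = {
    2: {(1, 1, 1): 1.0},
    4: {(1, 1, 2): 1.0 / 3.0},
    6: {(1, 1, 3): 0.1761263, (1, 2, 2): 0.1572071},
    8: {(1, 1, 4): 0.1209877, (1, 2, 3): 0.0907407, (2, 2, 2): 0.0925926},
}


@dataclass(frozen=True)
class QuadratureSet:
    """Directions (n, 3) and weights (n,) of an S_N set; sum(w) == 1."""

    order: int
    directions: np.ndarray
    weights: np.ndarray

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def to_csv(self, path) -> None:
        """Write (mu, eta, xi, w) rows for inspection."""
        arr = np.column_stack([self.directions, self.weights])
        np.savetxt(path, arr, delimiter=",", header="mu,eta,xi,w", comments="")


def _levels(N: int) -> np.ndarray:
    """Level cosines mu_i, i = 1..N/2, equally spaced in mu^2."""
    mu1 = _MU1[N]
    n = N // 2
    if n == 1:
        return np.array([mu1])
    delta = 2.0 * (1.0 - 3.0 * mu1 * mu1) / (N - 2)
    return np.sqrt(mu1 * mu1 + np.arange(n) * delta)


def _octant_points(N: int) -> list[tuple[int, int, int]]:
    """Level-index triples (i, j, k) >= 1 with i + j + k = N/2 + 2."""
    s = N // 2 + 2
    return [
        (i, j, s - i - j)
        for i in range(1, s)
        for j in range(1, s - i)
        if s - i - j >= 1
    ]


def _solve_weights(N: int, mu: np.ndarray, points) -> dict[tuple, float]:
    """Point-class weights matching even moments sum(w mu^2m) = 1/(2m+1).

    The full square system can turn negative at higher orders, so the weights
    are taken as the smallest deviation from equal point weights satisfying
    as many leading even-moment conditions as positivity allows.  The mu^0
    and mu^2 conditions hold exactly for any class weights summing to one per
    octant (a property of the equally-spaced-in-mu^2 level structure), so the
    sweep and scalar-fluence sums are unaffected by the fallback depth.
    """
    classes = sorted({tuple(sorted(p)) for p in points})
    ncls = len(classes)
    counts = np.array(
        [sum(1 for p in points if tuple(sorted(p)) == c) for c in classes], dtype=float
    )
    w_eq = np.full(ncls, 1.0 / len(points))
    A_full = np.zeros((ncls, ncls))
    b_full = np.zeros(ncls)
    for m in range(ncls):
        b_full[m] = 1.0 / (2 * m + 1)
        for ci, cls in enumerate(classes):
            A_full[m, ci] = sum(
                mu[p[0] - 1] ** (2 * m) for p in points if tuple(sorted(p)) == cls
            )
    for ncond in range(ncls, 0, -1):
        A = A_full[:ncond]
        b = b_full[:ncond]
        # minimum-norm correction to equal weights (per-point scaling by counts)
        delta, *_ = np.linalg.lstsq(A, b - A @ w_eq, rcond=None)
        w = w_eq + delta
        if np.all(w > 0) and np.allclose(A @ w, b, atol=1e-12):
            return dict(zip(classes, w))
    raise ValueError(f"could not construct positive weights for N={N}")  # pragma: no cover


def build_level_symmetric(N: int) -> QuadratureSet:
    """Build the LQ_N level-symmetric quadrature, N even in {2, 4, ..., 16}."""
    if N not in _MU1:
        raise ValueError(f"unsupported quadrature order N={N}; supported: {sorted(_MU1)}")
    mu = _levels(N)
    points = _octant_points(N)
    if N in _POINT_WEIGHTS:
        wmap = _POINT_WEIGHTS[N]
    else:
        wmap = _solve_weights(N, mu, points)
    dirs = []
    wts = []
    for (i, j, k) in points:
        base = np.array([mu[i - 1], mu[j - 1], mu[k - 1]])
        base /= np.linalg.norm(base)  # guard: exact by construction
        w = wmap[tuple(sorted((i, j, k)))] / 8.0
        for signs in itertools.product([1.0, -1.0], repeat=3):
            dirs.append(base * signs)
            wts.append(w)
    directions = np.array(dirs)
    weights = np.array(wts)
    weights = weights / weights.sum()
    q = QuadratureSet(N, directions, weights)
    assert q.n_directions == N * (N + 2)
    return q


def _legendre(l: int, x: np.ndarray) -> np.ndarray:
    c = np.zeros(l + 1)
    c[l] = 1.0
    return np.polynomial.legendre.legval(x, c)


def angular_moment(q: QuadratureSet, f, l: int, axis=(0.0, 0.0, 1.0)) -> float:
    """Quadrature moment sum_n w_n f_n P_l(Omega_n . axis)."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != q.n_directions:
        raise ValueError(f"f has {f.shape[0]} values for {q.n_directions} directions")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    mu = q.directions @ a
    return float(np.sum(q.weights * f * _legendre(l, mu)))
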