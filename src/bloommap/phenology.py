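"""Bloom phenology: smoothed growth curves, timing of maximum growth
(TMBAA), fuzzy c-means clustering of seasonal profiles, and growth windows.

The growth curve of a cell-year is the cumulative proportion of
bloom-affected pixels versus day of year.  It is smoothed with a penalized
cyclic cubic B-spline under a log link: the spline is fitted to the daily
*increments* of the cumulative curve (the quantity that is genuinely
periodic over the year), the smoothed density is integrated back into a
cumulative curve, and monotonicity is enforced by a running maximum.
Smoothing strength is chosen by generalized cross-validation with a fixed
effective-degrees-of-freedom fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.spatial.distance import cdist

PERIOD = 365.0

# growth windows per phenology cluster (day-of-year, inclusive)
WINDOW_FULL_YEAR = (1, 365)
WINDOW_CLUSTER_II = (150, 270)
SOUTHERN_SHIFT_DAYS = 183


@dataclass
class GrowthCurve:
    """Smoothed cumulative bloom-area proportion over days 1-365."""

    days: np.ndarray
    cumulative: np.ndarray
    density: np.ndarray  # smoothed daily increments (the periodic quantity)
    lam: float
    edf: float
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def flat(self) -> bool:
        return not (self.density > 0).any()


def cyclic_design(t, n_basis: int = 20, period: float = PERIOD) -> np.ndarray:
    """Design matrix of ``n_basis`` periodic cubic B-splines at times t."""
    h = period / n_basis
    knots = h * np.arange(-3, n_basis + 4)
    tm = np.mod(np.asarray(t, dtype=float), period)
    A = BSpline.design_matrix(tm, knots, 3).toarray()
    A[:, :3] += A[:, n_basis : n_basis + 3]
    return A[:, :n_basis]


def _cyclic_penalty(n_basis: int) -> np.ndarray:
    D = np.zeros((n_basis, n_basis))
    for i in range(n_basis):
        D[i, i] = -2.0
        D[i, (i - 1) % n_basis] = 1.0
        D[i, (i + 1) % n_basis] = 1.0
    return D.T @ D


def _penalized_fit(A: np.ndarray, z: np.ndarray, P: np.ndarray, lam: float):
    AtA = A.T @ A
    beta = solve(AtA + lam * P, A.T @ z, assume_a="pos")
    edf = float(np.trace(solve(AtA + lam * P, AtA, assume_a="pos")))
    resid = z - A @ beta
    return beta, edf, float(resid @ resid)


def growth_curve(
    proportions,
    days=None,
    n_basis: int = 20,
    eps: float = 1e-4,
    fallback_edf: float = 8.0,
) -> GrowthCurve:
    """Smooth one cell-year's cumulative bloom-area proportion.

    ``proportions`` is the cumulative affected-pixel proportion per day of
    year (non-finite entries are treated as unobserved days); at least 30
    valid days are required.  An all-zero input yields a flat zero curve.
    """
    y = np.asarray(proportions, dtype=float)
    if days is None:
        days = np.arange(1, y.size + 1, dtype=float)
    days = np.asarray(days, dtype=float)
    valid = np.isfinite(y)
    if valid.sum() < 30:
        raise ValueError("need at least 30 valid days to fit a growth curve")
    out_days = np.arange(1, 366, dtype=float)

    if not (y[valid] > 0).any():
        zero = np.zeros(out_days.size)
        return GrowthCurve(out_days, zero, zero.copy(), 0.0, 0.0, meta={"all_zero": True})

    # daily increments of the cumulative curve (>= 0)
    yv = y[valid]
    dv = days[valid]
    inc = np.diff(yv, prepend=0.0)
    inc = np.clip(inc, 0.0, None)
    z = np.log(inc + eps)

    A = cyclic_design(dv, n_basis)
    P = _cyclic_penalty(n_basis)
    n = z.size

    best = None
    converged = True
    for lam in np.logspace(-3.0, 5.0, 33):
        try:
            beta, edf, rss = _penalized_fit(A, z, P, lam)
        except np.linalg.LinAlgError:
            continue
        gcv = n * rss / (n - edf) ** 2 if edf < n else np.inf
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None or not np.isfinite(best[0]):
        # fallback: fixed effective df via bisection on lambda
        converged = False
        lo, hi = 1e-8, 1e12
        for _ in range(80):
            lam = np.sqrt(lo * hi)
            beta, edf, _ = _penalized_fit(A, z, P, lam)
            if edf > fallback_edf:
                lo = lam
            else:
                hi = lam
        best = (np.nan, lam, beta, edf)

    _, lam, beta, edf = best
    A_out = cyclic_design(out_days, n_basis)
    density = np.clip(np.exp(A_out @ beta) - eps, 0.0, None)
    cumulative = np.cumsum(density)
    y_end = yv[-1]
    if cumulative[-1] > 0 and y_end > 0:
        scale = y_end / cumulative[-1]
        cumulative *= scale
        density *= scale
    cumulative = np.clip(np.maximum.accumulate(cumulative), 0.0, 1.0)
    return GrowthCurve(
        out_days, cumulative, density, float(lam), float(edf), converged,
        meta={"n_basis": n_basis, "eps": eps, "n_valid_days": int(valid.sum())},
    )


def tmbaa(curve: GrowthCurve) -> int:
    """Timing of maximum bloom-affected-area growth: the day of the maximum
    first derivative of the smoothed cumulative curve (a sigmoid's
    inflection).  Ties break to the earliest day.  Undefined for a flat
    curve."""
    if curve.flat:
        raise ValueError("TMBAA is undefined for a flat growth curve")
    return int(curve.days[int(np.argmax(curve.density))])


@dataclass
class ClusterResult:
    """Fuzzy c-means result: row-stochastic memberships, hard labels,
    centroid curves."""

    memberships: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray
    n_iter: int
    converged: bool


def cluster_curves(
    curves,
    k: int = 3,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int = 0,
    archetypes: np.ndarray | None = None,
) -> ClusterResult:
    """Fuzzy c-means over growth-curve vectors.

    ``curves`` is (n_curves, n_days) (GrowthCurve objects are accepted and
    reduced to their cumulative vectors).  When ``archetypes`` (k reference
    centroid curves) is given, clusters are relabelled by the permutation
    that best matches them, so label i means archetype i (I/II/III order).
    """
    X = np.asarray(
        [c.cumulative if isinstance(c, GrowthCurve) else np.asarray(c, float) for c in curves],
        dtype=float,
    )
    n = X.shape[0]
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} curves")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    U = rng.random((n, k))
    U /= U.sum(axis=1, keepdims=True)

    m = fuzzifier
    V = np.zeros((k, X.shape[1]))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**m
        V_new = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, V_new, "sqeuclidean")
        # relative zero threshold so identical curves (centroids coincident
        # with every point to round-off) degrade to equal memberships
        zero = d2 <= 1e-12 * max(1.0, float((X**2).sum(axis=1).max()))
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            U = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            U[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        shift = float(np.abs(V_new - V).max()) if it > 1 else np.inf
        V = V_new
        if shift < tol:
            converged = True
            break

    order = np.arange(k)
    if archetypes is not None:
        archetypes = np.asarray(archetypes, dtype=float)
        if archetypes.shape != V.shape:
            raise ValueError("archetype centroids must be (k, n_days)")
        best_perm, best_cost = None, np.inf
        for perm in permutations(range(k)):
            cost = sum(np.sum((V[perm[i]] - archetypes[i]) ** 2) for i in range(k))
            if cost < best_cost:
                best_perm, best_cost = perm, cost
        order = np.asarray(best_perm)
        U = U[:, order]
        V = V[order]
    labels = np.argmax(U, axis=1)
    return ClusterResult(U, labels, V, it, converged)


ROMAN = {0: "I", 1: "II", 2: "III"}
_FROM_ROMAN = {v: k for k, v in ROMAN.items()}


def growth_window(cluster: int | str, hemisphere: str = "N") -> tuple[int, int]:
    """Day-of-year interval over which bloom drivers are averaged.

    Clusters I and III use the full year; cluster II uses days 150-270.
    Southern-hemisphere windows are expressed on the 183-day-shifted axis,
    so the cluster-II window wraps the calendar year (332 -> 87).
    """
    label = _FROM_ROMAN.get(cluster, cluster) if isinstance(cluster, str) else int(cluster)
    if label not in (0, 1, 2):
        raise ValueError(f"unknown cluster label {cluster!r}")
    window = WINDOW_CLUSTER_II if label == 1 else WINDOW_FULL_YEAR
    if hemisphere.upper().startswith("S"):
        if window == WINDOW_FULL_YEAR:
            return WINDOW_FULL_YEAR
        start = (window[0] - 1 - SOUTHERN_SHIFT_DAYS) % 365 + 1
        end = (window[1] - 1 - SOUTHERN_SHIFT_DAYS) % 365 + 1
        return (int(start), int(end))
    if not hemisphere.upper().startswith("N"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return window


def cumulative_proportions(states: np.ndarray) -> np.ndarray:
    """Daily cumulative proportion of ever-affected pixels for one
    cell-year, normalised by the year-end affected count (zero series if no
    pixel blooms)."""
    from .scene import BLOOM

    bloom = np.asarray(states) == BLOOM
    ever = np.maximum.accumulate(bloom, axis=0)
    counts = ever.reshape(ever.shape[0], -1).sum(axis=1).astype(float)
    if counts[-1] == 0:
        return counts
    return counts / counts[-1]
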