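"""Tetrachoric co-occurrence matrix, distance transform and Ward clustering.

The tetrachoric estimator is two-step: thresholds from the marginal normal
quantiles, then the latent correlation by maximising the bivariate-normal
likelihood of the 2x2 table.  Pairwise-complete observations (participants
exposed to both medications) feed each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats import norm

from .cohort import CohortTable
from .constants import ALL_EFFECTS, DRUGS
from .errors import ConfigError

logger = logging.getLogger(__name__)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def bvn_cdf(h: float, k: float, rho) -> np.ndarray | float:
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized over rho.

    Uses Gauss-Legendre integration of the Drezner-Wesolowsky identity
    d Phi2 / d rho = phi2(h, k; rho); falls back to scipy's mvn routine for
    |rho| > 0.925 where the integrand steepens.
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    out = np.empty_like(rho_arr)
    easy = np.abs(rho_arr) <= 0.925
    if easy.any():
        r = 0.5 * rho_arr[easy][:, None] * (_GL_NODES[None, :] + 1.0)  # [0, rho]
        omr2 = 1.0 - r**2
        integrand = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * omr2)) / np.sqrt(omr2)
        integral = 0.5 * rho_arr[easy] * (integrand @ _GL_WEIGHTS)
        out[easy] = norm.cdf(h) * norm.cdf(k) + integral / (2.0 * np.pi)
    for i in np.flatnonzero(~easy):
        r = float(rho_arr[i])
        out[i] = stats.multivariate_normal.cdf(
            [h, k], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
        )
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(rho) else float(out[0])


def _cell_probs(tau_x: float, tau_y: float, rho) -> tuple:
    """(p11, p10, p01, p00) for dichotomised bivariate normal."""
    p00 = bvn_cdf(tau_x, tau_y, rho)
    px, py = norm.cdf(tau_x), norm.cdf(tau_y)
    p10 = py - p00  # X above, Y below
    p01 = px - p00
    p11 = 1.0 - px - py + p00
    return p11, p10, p01, p00


@dataclass
class TetrachoricResult:
    rho: float  # NaN when undefined
    tau_x: float
    tau_y: float

    def __iter__(self):
        return iter((self.rho, self.tau_x, self.tau_y))


def tetrachoric(a: float, b: float, c: float, d: float) -> TetrachoricResult:
    """Latent correlation from a 2x2 table.

    ``a`` = both endorsed, ``b`` = first only, ``c`` = second only,
    ``d`` = neither.  A 0.5 continuity correction is applied to zero cells.
    Degenerate margins (a whole row or column empty) yield rho = NaN.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or cells.sum() < 2:
        raise ConfigError(f"invalid 2x2 table ({a}, {b}, {c}, {d})")
    a0, b0, c0, d0 = cells
    # degenerate margins are judged before continuity correction
    if (a0 + b0 == 0) or (c0 + d0 == 0) or (a0 + c0 == 0) or (b0 + d0 == 0):
        return TetrachoricResult(np.nan, np.nan, np.nan)
    # perfect association before correction
    if b0 == 0 and c0 == 0:
        n = cells.sum()
        return TetrachoricResult(
            1.0, float(norm.ppf((c0 + d0) / n)), float(norm.ppf((b0 + d0) / n))
        )
    if a0 == 0 and d0 == 0:
        n = cells.sum()
        return TetrachoricResult(
            -1.0, float(norm.ppf((c0 + d0) / n)), float(norm.ppf((b0 + d0) / n))
        )
    cells[cells == 0] += 0.5
    a1, b1, c1, d1 = cells
    n = cells.sum()
    tau_x = float(norm.ppf((c1 + d1) / n))  # threshold of the first variable
    tau_y = float(norm.ppf((b1 + d1) / n))

    def nll(rho: float) -> float:
        p = np.clip(_cell_probs(tau_x, tau_y, rho), 1e-300, None)
        return -(a1 * np.log(p[0]) + b1 * np.log(p[1]) + c1 * np.log(p[2]) + d1 * np.log(p[3]))

    res = optimize.minimize_scalar(nll, bounds=(-0.9999, 0.9999), method="bounded",
                                   options={"xatol": 1e-10})
    return TetrachoricResult(float(res.x), tau_x, tau_y)


# ---------------------------------------------------------------------------
# Pairwise-complete matrix over medication x side-effect columns
# ---------------------------------------------------------------------------


@dataclass
class TetraMatrix:
    labels: list[tuple[str, str]]  # (medication, side_effect)
    rho: np.ndarray
    n_pair: np.ndarray
    cell_counts: np.ndarray  # (p, p, 4) tables (a, b, c, d)


def tetra_matrix(
    cohort: CohortTable,
    effects: tuple[str, ...] = ALL_EFFECTS,
    medications: tuple[str, ...] = DRUGS,
    min_pair_n: int = 30,
) -> TetraMatrix:
    """Tetrachoric correlations across all medication x side-effect columns.

    Each pair is evaluated on participants exposed to both medications; pairs
    with fewer than ``min_pair_n`` complete observations (or degenerate
    margins) are flagged undefined (NaN).
    """
    labels = [(d, e) for d in medications for e in effects]
    p = len(labels)
    n = len(cohort)
    E = np.empty((n, p))
    for j, (d, e) in enumerate(labels):
        E[:, j] = cohort.endorsement(d, e)
    O = ~np.isnan(E)  # observed mask
    A = np.nan_to_num(E)  # 1 where endorsed, 0 elsewhere

    # joint counts by matrix products over the observed masks
    Of = O.astype(float)
    n11 = A.T @ A
    n1_ = A.T @ Of  # first endorsed, second observed
    n_1 = Of.T @ A
    npair = Of.T @ Of
    n10 = n1_ - n11
    n01 = n_1 - n11
    n00 = npair - n11 - n10 - n01

    rho = np.full((p, p), np.nan)
    cells = np.stack([n11, n10, n01, n00], axis=-1)
    np.fill_diagonal(rho, 1.0)
    n_undef = 0
    for i in range(p):
        for j in range(i + 1, p):
            if npair[i, j] < max(min_pair_n, 2):
                n_undef += 1
                continue
            r = tetrachoric(n11[i, j], n10[i, j], n01[i, j], n00[i, j]).rho
            if np.isnan(r):
                n_undef += 1
            rho[i, j] = rho[j, i] = r
    if n_undef:
        logger.info("tetra_matrix: %d of %d pairs undefined", n_undef, p * (p - 1) // 2)
    return TetraMatrix(labels=labels, rho=rho, n_pair=npair.astype(int), cell_counts=cells)


@dataclass
class DistanceMatrix:
    labels: list[tuple[str, str]]
    d: np.ndarray
    n_imputed: int
    dropped: list[tuple[str, str]]


def corr_to_dist(m: TetraMatrix) -> DistanceMatrix:
    """d = 1 - rho.  Columns with no defined off-diagonal correlation are
    dropped; remaining undefined cells are imputed to the median defined
    distance (count logged)."""
    rho = m.rho.copy()
    p = rho.shape[0]
    off = ~np.eye(p, dtype=bool)
    defined_per_col = np.sum(~np.isnan(rho) & off, axis=0)
    keep = defined_per_col > 0
    dropped = [m.labels[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.info("corr_to_dist: dropping %d all-undefined columns", len(dropped))
    rho = rho[np.ix_(keep, keep)]
    labels = [m.labels[i] for i in np.flatnonzero(keep)]
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    undefined = np.isnan(d)
    n_imputed = int(undefined.sum() // 2)
    if n_imputed:
        med = np.nanmedian(d[~np.eye(len(labels), dtype=bool)])
        d[undefined] = med
        logger.info("corr_to_dist: imputed %d undefined pairs to median %.4f", n_imputed, med)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels=labels, d=d, n_imputed=n_imputed, dropped=dropped)


# ---------------------------------------------------------------------------
# Ward minimum-variance clustering (Lance-Williams recurrence)
# ---------------------------------------------------------------------------


@dataclass
class LinkageTree:
    merges: list[tuple[int, int, float, int]]  # (node_a, node_b, height, size)
    leaf_order: list[int]
    n_leaves: int

    def to_scipy(self) -> np.ndarray:
        """(n-1) x 4 linkage array in scipy.cluster.hierarchy layout."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels for the given number of clusters."""
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.to_scipy(), n_clusters, criterion="maxclust")


def ward_cluster(dist: np.ndarray | DistanceMatrix) -> LinkageTree:
    """Agglomerative minimum-variance clustering.

    Operates on squared dissimilarities with the Ward Lance-Williams update;
    heights follow the scipy convention (sqrt of the updated squared cluster
    distance, so two singletons merge at their input distance).  Ties are
    broken by the lowest pair of cluster indices, making the tree
    deterministic.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ConfigError("distance matrix contains non-finite entries")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ConfigError("distance matrix must be square and symmetric")
    n = d.shape[0]
    D2 = d.astype(float) ** 2
    np.fill_diagonal(D2, np.inf)
    size = np.ones(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    node_id = np.arange(n)  # active row -> dendrogram node id
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    children: dict[int, tuple[int, int]] = {}

    for _ in range(n - 1):
        # row-major argmin of the symmetric matrix lands on the (i, j) pair
        # with the lowest indices among ties
        flat = int(np.argmin(D2))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h2 = float(D2[i, j])
        height = float(np.sqrt(max(h2, 0.0)))
        ni, nj = int(size[i]), int(size[j])
        # Lance-Williams Ward update against every other active cluster
        others = alive.copy()
        others[[i, j]] = False
        nk = size[others]
        upd = ((ni + nk) * D2[i, others] + (nj + nk) * D2[j, others] - nk * h2) / (
            ni + nj + nk
        )
        D2[i, others] = upd
        D2[others, i] = upd
        na, nb = int(node_id[i]), int(node_id[j])
        if na > nb:
            na, nb = nb, na
        merges.append((na, nb, height, ni + nj))
        children[next_id] = (na, nb)
        size[i] = ni + nj
        node_id[i] = next_id
        next_id += 1
        alive[j] = False
        D2[j, :] = np.inf
        D2[:, j] = np.inf

    # left-to-right dendrogram leaf order
    order: list[int] = []

    def _walk(node: int) -> None:
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            _walk(a)
            _walk(b)

    _walk(next_id - 1)
    return LinkageTree(merges=merges, leaf_order=order, n_leaves=n)


# ---------------------------------------------------------------------------
# Co-occurrence medians
# ---------------------------------------------------------------------------


def summarize_cooccurrence(m: TetraMatrix) -> dict:
    """Median rho within-side-effect (across medications), within-medication
    (across side effects) and across-both pairs.  Empty categories are None."""
    p = len(m.labels)
    cats: dict[str, list[float]] = {
        "within_side_effect": [],
        "within_medication": [],
        "across": [],
    }
    for i in range(p):
        di, ei = m.labels[i]
        for j in range(i + 1, p):
            r = m.rho[i, j]
            if np.isnan(r):
                continue
            dj, ej = m.labels[j]
            if ei == ej and di != dj:
                cats["within_side_effect"].append(r)
            elif di == dj and ei != ej:
                cats["within_medication"].append(r)
            elif di != dj and ei != ej:
                cats["across"].append(r)
    return {
        key: (float(np.median(v)) if v else None) for key, v in cats.items()
    } | {f"n_{key}": len(v) for key, v in cats.items()}
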