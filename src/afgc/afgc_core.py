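"""Vector-autoregressive Granger causality on the differenced panel.

Each cell's differenced series is regressed by OLS on ``p`` lags of every
cell's series (plus an intercept).  Cell ``j`` Granger-causes cell ``i``
when deleting all of ``j``'s lags from ``i``'s regression significantly
inflates the residual sum of squares; significance comes from the nested
F statistic

    F = ((RSS_B - RSS_A) / p) / (RSS_A / (n - K*p - 1))

with RSS_A from the full and RSS_B from the restricted model on the same
row set, referred to an F(p, n - K*p - 1) distribution.  Running the test
for every ordered pair and thresholding the p-values reconstructs the
directed network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_sim import DirectedNetwork
from .preprocess import DifferencedPanel

__all__ = [
    "VarFit",
    "GCTest",
    "InferredNetwork",
    "build_design",
    "fit_var",
    "gc_test",
    "reconstruct_network",
    "P_FLOOR",
    "LOG10_P_FLOOR",
]

# p-values below the double-precision floor are reported as the floor;
# log-scale comparisons are capped there as well
P_FLOOR = 1e-320
LOG10_P_FLOOR = -320.0
DEFAULT_ORDER = 5


def build_design(panel: DifferencedPanel, p: int,
                 drop_boundary_rows: bool = True) -> tuple:
    """Lagged design matrix and response for a VAR(p) on the panel.

    Returns ``(X, Y)`` where row t of ``X`` is the concatenation
    ``[D[t-1], D[t-2], ..., D[t-p]]`` (lag-major, cells within lag) and
    ``Y[t] = D[t]``.  With ``drop_boundary_rows`` (default) every row whose
    lag window spans a segment join is removed, so no regression equation
    mixes samples from different rising segments; disabling it treats the
    concatenation as one unbroken series.
    """
    D = panel.values
    T, K = D.shape
    if T <= p:
        raise ValueError(f"panel of {T} points cannot support order {p}")
    X = np.empty((T - p, K * p))
    for lag in range(1, p + 1):
        X[:, (lag - 1) * K: lag * K] = D[p - lag: T - lag]
    Y = D[p:]
    if drop_boundary_rows:
        keep = np.ones(T - p, dtype=bool)
        for b in panel.segment_boundaries:
            # response rows t in [b, b+p) have lag windows crossing the join
            lo = max(b - p, 0)
            hi = min(b, T - p)
            keep[lo:hi] = False
        X, Y = X[keep], Y[keep]
    return X, Y


@dataclass
class VarFit:
    """OLS fit of a VAR(p): one regression per response cell."""

    order: int
    intercept: np.ndarray        # (K,)
    coefficients: np.ndarray     # (K responses, K sources, p lags)
    residuals: np.ndarray        # (n_used, K)
    rss: np.ndarray              # (K,)
    n_used: int
    dropped_boundary_rows: bool

    @property
    def n_cells(self) -> int:
        return self.coefficients.shape[0]

    def residual_variance(self) -> np.ndarray:
        """sigma^2 estimates: RSS / (n - K*p - 1) per response."""
        df = self.n_used - self.n_cells * self.order - 1
        return self.rss / df


def _ols(X1: np.ndarray, Y: np.ndarray) -> tuple:
    """Least-squares fit with rank check. Returns (coef, resid, rss)."""
    coef, _, rank, _ = np.linalg.lstsq(X1, Y, rcond=None)
    if rank < X1.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X1.shape[1]}): "
            "collinear or constant inputs")
    resid = Y - X1 @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return coef, resid, rss


def fit_var(panel: DifferencedPanel, p: int = DEFAULT_ORDER,
            drop_boundary_rows: bool = True) -> VarFit:
    """Fit the full VAR(p) by per-response OLS with intercept."""
    X, Y = build_design(panel, p, drop_boundary_rows)
    n, K = Y.shape
    if n <= K * p + 1:
        raise ValueError(
            f"insufficient observations: {n} rows for {K * p + 1} parameters")
    X1 = np.hstack([np.ones((n, 1)), X])
    coef, resid, rss = _ols(X1, Y)
    # coef rows: [intercept, lag1 cells 0..K-1, lag2 ..., lagp ...]
    intercept = coef[0]
    A = coef[1:].reshape(p, K, K)           # (lag, source, response)
    coefficients = np.transpose(A, (2, 1, 0))  # (response, source, lag)
    return VarFit(order=p, intercept=intercept, coefficients=coefficients,
                  residuals=resid, rss=rss, n_used=n,
                  dropped_boundary_rows=drop_boundary_rows)


@dataclass
class GCTest:
    """Nested F test of whether source cell j Granger-causes response i."""

    response: int
    source: int
    sigma2_full: float
    sigma2_restricted: float
    f_statistic: float
    df: tuple
    p_value: float

    @property
    def log10_p(self) -> float:
        return max(np.log10(max(self.p_value, 0.0) + 0.0) if self.p_value > 0
                   else LOG10_P_FLOOR, LOG10_P_FLOOR)


def _gc_from_rss(rss_full: float, rss_restricted: float, p: int,
                 df2: int, response: int, source: int) -> GCTest:
    # nesting can only be violated by floating-point jitter; clip
    rss_restricted = max(rss_restricted, rss_full)
    f_stat = ((rss_restricted - rss_full) / p) / (rss_full / df2)
    p_value = float(stats.f.sf(f_stat, p, df2))
    return GCTest(response=response, source=source,
                  sigma2_full=rss_full / df2,
                  sigma2_restricted=rss_restricted / df2,
                  f_statistic=float(f_stat), df=(p, df2),
                  p_value=max(p_value, P_FLOOR) if p_value > 0 else P_FLOOR)


def gc_test(panel: DifferencedPanel, p: int, response: int, source: int,
            drop_boundary_rows: bool = True) -> GCTest:
    """Test whether ``source`` Granger-causes ``response`` at order p.

    Both the full and the restricted model are fit to the identical row
    set, as nested-F validity requires.
    """
    if response == source:
        raise ValueError("no self-tests: response must differ from source")
    X, Y = build_design(panel, p, drop_boundary_rows)
    n, K = Y.shape
    if n <= K * p + 1:
        raise ValueError("insufficient observations")
    X1 = np.hstack([np.ones((n, 1)), X])
    _, _, rss_full = _ols(X1, Y[:, [response]])
    cols = [0] + [1 + lag * K + j for lag in range(p) for j in range(K)
                  if j != source]
    _, _, rss_restr = _ols(X1[:, cols], Y[:, [response]])
    df2 = n - K * p - 1
    return _gc_from_rss(float(rss_full[0]), float(rss_restr[0]), p, df2,
                        response, source)


@dataclass
class InferredNetwork:
    """Full K x K score table of pairwise Granger tests.

    ``f_matrix[j, i]`` and ``p_matrix[j, i]`` score the ordered pair
    (source j -> response i); the diagonal is undefined (NaN).
    """

    f_matrix: np.ndarray
    p_matrix: np.ndarray
    order: int
    n_used: int
    method: str = "plain"

    @property
    def n_cells(self) -> int:
        return self.p_matrix.shape[0]

    def scores(self) -> np.ndarray:
        """-log10 p per ordered pair, floored; the edge-ranking score."""
        with np.errstate(divide="ignore"):
            s = -np.log10(np.maximum(self.p_matrix, P_FLOOR))
        return s

    def threshold(self, level: float = 0.05,
                  bonferroni: bool = True) -> DirectedNetwork:
        """Binary network: keep pairs with p below the level (optionally
        Bonferroni-corrected over the K*(K-1) tests)."""
        K = self.n_cells
        cut = level / (K * (K - 1)) if bonferroni else level
        edges = []
        scores = {}
        for j in range(K):
            for i in range(K):
                if i == j:
                    continue
                if self.p_matrix[j, i] < cut:
                    edges.append((j, i))
                    scores[(j, i)] = float(self.f_matrix[j, i])
        return DirectedNetwork(n_cells=K, edges=tuple(edges), scores=scores)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "F", "p_value", "method"])
            K = self.n_cells
            for j in range(K):
                for i in range(K):
                    if i == j:
                        continue
                    w.writerow([j, i, repr(float(self.f_matrix[j, i])),
                                repr(float(self.p_matrix[j, i])), self.method])

    @classmethod
    def read_csv(cls, path) -> "InferredNetwork":
        rows = []
        with open(path, newline="") as fh:
            rd = csv.DictReader(fh)
            for row in rd:
                rows.append((int(row["source"]), int(row["target"]),
                             float(row["F"]), float(row["p_value"]),
                             row.get("method", "plain")))
        K = 1 + max(max(r[0], r[1]) for r in rows)
        f_m = np.full((K, K), np.nan)
        p_m = np.full((K, K), np.nan)
        for j, i, f, pv, method in rows:
            f_m[j, i] = f
            p_m[j, i] = pv
        return cls(f_matrix=f_m, p_matrix=p_m, order=0, n_used=0,
                   method=rows[0][4] if rows else "plain")


def reconstruct_network(panel: DifferencedPanel, p: int = DEFAULT_ORDER,
                        drop_boundary_rows: bool = True) -> InferredNetwork:
    """Pairwise Granger tests for every ordered pair of cells.

    The full model is fit once; each restricted model (one per source cell)
    is fit once and shared across responses, so the cost is K+1 least
    squares solves.  The full score table is retained regardless of any
    later thresholding.
    """
    X, Y = build_design(panel, p, drop_boundary_rows)
    n, K = Y.shape
    if K < 2:
        raise ValueError("need at least 2 cells")
    if n <= K * p + 1:
        raise ValueError("insufficient observations")
    X1 = np.hstack([np.ones((n, 1)), X])
    _, _, rss_full = _ols(X1, Y)
    df2 = n - K * p - 1
    f_m = np.full((K, K), np.nan)
    p_m = np.full((K, K), np.nan)
    for j in range(K):
        cols = [0] + [1 + lag * K + jj for lag in range(p) for jj in range(K)
                      if jj != j]
        _, _, rss_restr = _ols(X1[:, cols], Y)
        for i in range(K):
            if i == j:
                continue
            t = _gc_from_rss(float(rss_full[i]), float(rss_restr[i]), p, df2,
                             response=i, source=j)
            f_m[j, i] = t.f_statistic
            p_m[j, i] = t.p_value
    return InferredNetwork(f_matrix=f_m, p_matrix=p_m, order=p, n_used=n)
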