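"""Lasso-path regression of windowed peak density on genomic covariates.

The path is computed by least-angle regression with the lasso modification
(variables can leave the active set when a coefficient crosses zero), in the
lambda parametrisation: at every point on the path the active covariates
satisfy ``x_j' (y - X beta) = lambda * sign(beta_j)`` and no inactive
covariate exceeds ``lambda`` in absolute correlation.  Each covariate
entering the path is scored with the covariance test statistic, which is
asymptotically Exp(1) under the null of no remaining signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np

from rdipkit.genome_io import FeatureSet, GenomicInterval, overlap_bp

__all__ = [
    "DesignMatrix",
    "LassoPathResult",
    "CovTestEntry",
    "standardize",
    "build_design",
    "lars_lasso_path",
    "coefficients_at",
    "covariance_test",
    "entry_report",
]

_EPS = 1e-12


@dataclasses.dataclass
class DesignMatrix:
    """Standardized design: column means 0, column norms 1; centered response."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class LassoPathResult:
    """Knots, coefficients and events of a lasso path.

    ``knots`` are strictly decreasing lambda values; ``betas[k]`` is the
    coefficient vector at ``knots[k]``.  ``events[k]`` is ('enter'|'drop',
    variable index) describing what happens AT that knot ('end' for the
    terminal knot).  ``entry_order`` lists variables by first entry.
    """

    knots: np.ndarray
    betas: np.ndarray
    events: list[tuple[str, int]]
    entry_order: list[int]
    names: list[str]


@dataclasses.dataclass(frozen=True)
class CovTestEntry:
    rank: int
    index: int
    name: str
    lambda_entry: float
    statistic: float
    p_value: float


def standardize(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> DesignMatrix:
    """Center y; center each column of X and scale it to unit L2 norm.

    Constant (zero-variance) columns are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    keep = norms > _EPS * max(1.0, float(np.abs(X).max()))
    dropped = [names[j] for j in range(X.shape[1]) if not keep[j]]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
    Xc = Xc[:, keep] / norms[keep]
    if Xc.shape[1] < 2:
        raise ValueError("need at least 2 usable (non-constant) covariates")
    return DesignMatrix(
        X=Xc, y=y - y.mean(), names=[n for n, k in zip(names, keep) if k]
    )


def _window_index(
    windows: Sequence[GenomicInterval],
) -> dict[str, list[tuple[int, int, int]]]:
    idx: dict[str, list[tuple[int, int, int]]] = {}
    for i, w in enumerate(windows):
        idx.setdefault(w.chrom, []).append((w.start, w.end, i))
    for chrom in idx:
        idx[chrom].sort()
    return idx


def build_design(
    peaks: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
    feature_sets: Sequence[FeatureSet] = (),
    tracks: Mapping[str, Sequence[tuple[str, int, int, float]]] | None = None,
    covariate_table: Mapping[str, Sequence[float]] | None = None,
) -> DesignMatrix:
    """Assemble the window-level design matrix and peak-density response.

    Response: peaks assigned to windows by midpoint, counts rescaled by true
    window width to full-window equivalents, then centered.  Covariates:
    per-window occupied-bp fraction for each feature set, per-window mean for
    each bedGraph-style track, plus any precomputed per-window columns in
    ``covariate_table``.  Columns are standardized; constants dropped.
    """
    widx = _window_index(windows)
    counts = np.zeros(len(windows))
    for peak in peaks:
        mid = (peak.start + peak.end) // 2
        for start, end, i in widx.get(peak.chrom, ()):
            if start <= mid < end:
                counts[i] += 1
                break
    widths = np.array([len(w) for w in windows], dtype=float)
    nominal = widths.max()
    response = counts * (nominal / widths)

    columns: list[np.ndarray] = []
    names: list[str] = []
    for fs in feature_sets:
        col = np.array(
            [
                overlap_bp([w], fs.intervals, strict_namespace=False) / len(w)
                for w in windows
            ]
        )
        columns.append(col)
        names.append(fs.label)
    for track_name, rows in (tracks or {}).items():
        sums = np.zeros(len(windows))
        bps = np.zeros(len(windows))
        for chrom, start, end, value in rows:
            for wstart, wend, i in widx.get(chrom, ()):
                lo, hi = max(start, wstart), min(end, wend)
                if hi > lo:
                    sums[i] += value * (hi - lo)
                    bps[i] += hi - lo
        with np.errstate(invalid="ignore"):
            columns.append(np.where(bps > 0, sums / np.maximum(bps, 1), 0.0))
        names.append(track_name)
    for name, values in (covariate_table or {}).items():
        col = np.asarray(values, dtype=float)
        if len(col) != len(windows):
            raise ValueError(f"covariate {name!r} has wrong length")
        columns.append(col)
        names.append(name)
    if len(columns) < 2:
        raise ValueError("need at least 2 covariates")
    return standardize(np.column_stack(columns), response, names)


def lars_lasso_path(
    design: DesignMatrix, tol: float = 1e-10, max_events: int | None = None
) -> LassoPathResult:
    """Exact lasso coefficient path by LARS with the lasso modification.

    On each segment the active coefficients are affine in lambda:
    ``beta_A(lam) = G^{-1} (X_A' y - lam * s_A)`` with ``G = X_A' X_A``; the
    next knot is the largest lambda below the current one at which either an
    inactive covariate's correlation reaches lambda (entry) or an active
    coefficient hits zero (drop).  The path terminates at lambda = 0 with
    the least-squares fit on the final active set, or earlier after
    ``max_events`` knots when a truncated path suffices.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    c0 = X.T @ y
    lam = float(np.max(np.abs(c0)))
    j_first = int(np.argmax(np.abs(c0)))

    knots: list[float] = [lam]
    betas: list[np.ndarray] = [np.zeros(p)]
    events: list[tuple[str, int]] = [("enter", j_first)]
    entry_order: list[int] = [j_first]

    active: list[int] = [j_first]
    signs: dict[int, float] = {j_first: float(np.sign(c0[j_first]))}
    beta = np.zeros(p)
    max_active = min(n - 1, p) if n - 1 >= 1 else p

    while lam > tol:
        if max_events is not None and len(knots) >= max_events:
            break
        A = active
        XA = X[:, A]
        G = XA.T @ XA
        s_A = np.array([signs[j] for j in A])
        try:
            b0 = np.linalg.solve(G, XA.T @ y)
            d = np.linalg.solve(G, s_A)
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient active set; path truncated", stacklevel=2)
            break
        # beta_A(l) = b0 - l * d for l in (next knot, lam]
        inactive = [j for j in range(p) if j not in active]
        cand_lam = -np.inf
        cand_event: tuple[str, int] | None = None
        if inactive and len(active) < max_active:
            XI = X[:, inactive]
            a = XI.T @ y - XI.T @ (XA @ b0)
            b = XI.T @ (XA @ d)
            for idx, j in enumerate(inactive):
                for target in (+1.0, -1.0):
                    denom = target - b[idx]
                    if abs(denom) < _EPS:
                        continue
                    l_cand = a[idx] / denom if target > 0 else a[idx] / denom
                    # solve a + l*b = target*l  =>  l = a / (target - b)
                    if tol < l_cand < lam * (1 - 1e-9):
                        if l_cand > cand_lam:
                            cand_lam = l_cand
                            cand_event = ("enter", j)
        for pos, j in enumerate(A):
            if abs(d[pos]) < _EPS:
                continue
            l_cand = b0[pos] / d[pos]
            if tol < l_cand < lam * (1 - 1e-9) and l_cand > cand_lam:
                cand_lam = l_cand
                cand_event = ("drop", j)

        if cand_event is None:
            beta = np.zeros(p)
            beta[A] = b0
            knots.append(0.0)
            betas.append(beta.copy())
            events.append(("end", -1))
            lam = 0.0
            break

        lam = float(cand_lam)
        beta = np.zeros(p)
        beta[A] = b0 - lam * d
        kind, j = cand_event
        if kind == "enter":
            # sign of the entering covariate's correlation at the knot
            cj = float(X[:, j] @ (y - X @ beta))
            signs[j] = 1.0 if cj > 0 else -1.0
            active.append(j)
            if j not in entry_order:
                entry_order.append(j)
        else:
            beta[j] = 0.0
            active.remove(j)
            signs.pop(j)
        knots.append(lam)
        betas.append(beta.copy())
        events.append(cand_event)
        if not active:
            break

    return LassoPathResult(
        knots=np.array(knots),
        betas=np.array(betas),
        events=events,
        entry_order=entry_order,
        names=list(design.names),
    )


def coefficients_at(path: LassoPathResult, lam: float) -> np.ndarray:
    """Exact coefficients at any lambda, by interpolation between knots.

    Coefficients are piecewise linear in lambda, so linear interpolation on
    the knot grid is exact.  Above the first knot the solution is zero; below
    the last knot the last knot's solution is returned.
    """
    knots = path.knots
    if lam >= knots[0]:
        return np.zeros(path.betas.shape[1])
    if lam <= knots[-1]:
        return path.betas[-1].copy()
    k = int(np.searchsorted(-knots, -lam, "right")) - 1  # knots descending
    lo, hi = knots[k + 1], knots[k]
    w = (lam - lo) / (hi - lo) if hi > lo else 0.0
    return w * path.betas[k] + (1 - w) * path.betas[k + 1]


def _sigma2(design: DesignMatrix, path: LassoPathResult) -> float:
    """Noise-variance estimate: full OLS when n > p + 1, else path end."""
    n, p = design.n, design.p
    if n > p + 1:
        coef, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        rss = float(np.sum((design.y - design.X @ coef) ** 2))
        return rss / (n - p - 1)
    beta_end = path.betas[-1]
    df = int(np.sum(beta_end != 0))
    rss = float(np.sum((design.y - design.X @ beta_end) ** 2))
    denom = max(n - df - 1, 1)
    return rss / denom


def covariance_test(
    path: LassoPathResult,
    design: DesignMatrix,
    sigma2: float | None = None,
) -> list[CovTestEntry]:
    """Covariance test statistic and Exp(1) p-value per path entry.

    For the k-th entry knot ``lam_k`` with next knot ``lam_{k+1}``:
    ``T_k = (<y, X beta(lam_{k+1})> - <y, X_A beta~_A(lam_{k+1})>) / sigma2``
    where ``A`` is the active set just before the entry and ``beta~_A`` is
    the lasso path restricted to ``A`` evaluated at ``lam_{k+1}``.  Small
    negative values from floating-point cancellation are clamped to 0.
    """
    if sigma2 is None:
        sigma2 = _sigma2(design, path)
    if sigma2 <= 0:
        raise ValueError("degenerate response: estimated noise variance is 0")
    y = design.y
    X = design.X

    # reconstruct the active set before each knot
    active_before: list[list[int]] = []
    current: list[int] = []
    for kind, j in path.events:
        active_before.append(list(current))
        if kind == "enter":
            current.append(j)
        elif kind == "drop":
            current.remove(j)

    subpath_cache: dict[tuple[int, ...], LassoPathResult | None] = {}
    out: list[CovTestEntry] = []
    rank = 0
    for k, (kind, j) in enumerate(path.events):
        if kind != "enter":
            continue
        rank += 1
        if k + 1 >= len(path.knots):
            break  # truncated path: no next knot to evaluate this entry at
        lam_next = path.knots[k + 1]
        full_fit = float(y @ (X @ coefficients_at(path, lam_next)))
        A = active_before[k]
        if A:
            key = tuple(sorted(A))
            if key not in subpath_cache:
                sub_design = DesignMatrix(
                    X=X[:, list(key)], y=y, names=[path.names[i] for i in key]
                )
                subpath_cache[key] = lars_lasso_path(sub_design)
            sub = subpath_cache[key]
            restricted_fit = float(
                y @ (X[:, list(key)] @ coefficients_at(sub, lam_next))
            )
        else:
            restricted_fit = 0.0
        stat = max(0.0, (full_fit - restricted_fit) / sigma2)
        out.append(
            CovTestEntry(
                rank=rank,
                index=j,
                name=path.names[j],
                lambda_entry=float(path.knots[k]),
                statistic=stat,
                p_value=float(np.exp(-stat)),
            )
        )
    return out


def entry_report(
    entries: Sequence[CovTestEntry], alpha: float = 0.05
) -> tuple[list[dict], int]:
    """Ordered entry table plus the count of entries significant at alpha."""
    rows = [
        {
            "rank": e.rank,
            "covariate": e.name,
            "lambda_entry": e.lambda_entry,
            "statistic": e.statistic,
            "p_value": e.p_value,
            "significant": e.p_value < alpha,
        }
        for e in entries
    ]
    return rows, sum(r["significant"] for r in rows)
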