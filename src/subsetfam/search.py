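"""Candidate-subset enumeration on pseudo-data.

Subsets of a fixed size are ordered by the weighted residual sum of squares
of the pseudo-response (model fitted values, or the logistic working
response for classification) on the active columns, so the search reduces
to classical best-subsets regression with the fit standing in for the data.
The branch-and-bound enumerator returns, for every size ``k``, exactly the
``m_k`` subsets with smallest weighted RSS — identical as a set to
exhaustive enumeration — by pruning a Furnival–Wilson-style inclusion tree
with the monotone bound RSS(S) >= RSS(S') for S ⊆ S'.

Screening (for moderate-to-large p) keeps the intercept plus the columns
with the largest absolute standardized posterior-mean coefficients.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .actions import Subset, WeightScheme
from .design import DesignMatrix
from .posterior import PosteriorDraws

__all__ = [
    "SearchConfig",
    "CandidateSet",
    "screen_covariates",
    "branch_and_bound",
    "exhaustive_search",
    "forward_search",
    "backward_search",
    "search_candidates",
]

_EXHAUSTIVE_MAX_P = 25


@dataclass(frozen=True)
class SearchConfig:
    """Settings for candidate-subset enumeration.

    ``m_k`` caps the number of subsets retained per size; ``s_max`` caps
    the total number of columns (including the intercept) considered.
    """

    m_k: int = 15
    s_max: int = 35
    strategy: str = "bba"
    force_intercept: bool = True

    def __post_init__(self):
        if self.m_k < 1:
            raise ValueError("m_k must be at least 1")
        if self.s_max < 1:
            raise ValueError("s_max must be at least 1")
        if self.strategy not in ("bba", "exhaustive", "forward", "backward"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class CandidateSet:
    """Filtered collection of subsets: the best ``m_k`` of each size.

    ``by_size`` maps total subset size (including the intercept when
    forced) to a list of ``(Subset, rss)`` pairs sorted ascending by RSS.
    """

    by_size: dict[int, list[tuple[Subset, float]]]
    screened_columns: tuple[int, ...]
    config: SearchConfig

    def __iter__(self):
        for k in sorted(self.by_size):
            yield from self.by_size[k]

    def subsets(self) -> list[Subset]:
        return [s for s, _ in self]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_size.values())

    def to_records(self) -> list[dict]:
        return [
            {"k": k, "indices": list(s.indices), "rss": float(r)}
            for k in sorted(self.by_size)
            for s, r in self.by_size[k]
        ]

    @classmethod
    def from_records(
        cls, records, screened_columns=(), config: SearchConfig | None = None
    ) -> "CandidateSet":
        by_size: dict[int, list] = {}
        for rec in records:
            by_size.setdefault(int(rec["k"]), []).append(
                (Subset(tuple(rec["indices"])), float(rec["rss"]))
            )
        return cls(by_size, tuple(screened_columns), config or SearchConfig())


def screen_covariates(
    fit: PosteriorDraws, X: DesignMatrix, s_max: int
) -> np.ndarray:
    """Indices of the intercept plus the ``s_max - 1`` columns with largest
    absolute standardized posterior-mean coefficient.

    Standardization multiplies each coefficient by its column's sample
    standard deviation, so screening is invariant to column scaling.  Ties
    are broken by (lower) column index.
    """
    p1 = X.n_columns
    if s_max > p1:
        warnings.warn(f"s_max={s_max} exceeds column count {p1}; clipping")
        s_max = p1
    if s_max == p1:
        return np.arange(p1)
    coef = fit.mean[1:]
    sds = X.values[:, 1:].std(axis=0, ddof=1)
    mag = np.abs(coef * sds)
    # stable under ties: lexsort is stable, secondary key = column index
    order = np.lexsort((np.arange(mag.size), -mag))
    keep = np.sort(order[: s_max - 1]) + 1
    return np.concatenate([[0], keep])


# ---------------------------------------------------------------------------
# weighted pseudo-data preparation
# ---------------------------------------------------------------------------


def _prepare(target, pseudo_y, w, columns, force_intercept):
    """Weighted (and intercept-projected) Gram system for the search.

    Returns (cand_cols, G, bvec, yty, base_size) where ``cand_cols`` are
    the original column indices of the candidate (searchable) columns.
    With a forced intercept, the intercept is projected out: candidate
    columns and the pseudo-response are replaced by their weighted-mean
    residuals, and RSS values are those of the subset plus the intercept.
    """
    pseudo_y = np.asarray(pseudo_y, dtype=float)
    columns = np.asarray(columns, dtype=int)
    sw = np.sqrt(w.omega)
    if force_intercept:
        if 0 not in columns:
            columns = np.concatenate([[0], columns])
        cand = columns[columns != 0]
        A = target.columns(cand) * sw[:, None]
        b = pseudo_y * sw
        s0 = sw / np.linalg.norm(sw)
        A = A - np.outer(s0, s0 @ A)
        b = b - s0 * (s0 @ b)
        base_size = 1
    else:
        cand = columns
        A = target.columns(cand) * sw[:, None]
        b = pseudo_y * sw
        base_size = 0
    G = A.T @ A
    bvec = A.T @ b
    yty = float(b @ b)
    return cand, G, bvec, yty, base_size


# ---------------------------------------------------------------------------
# branch-and-bound kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _insert(res_rss, res_mask, counts, thr, k, rss, mask, m_k):
    cnt = counts[k]
    if cnt < m_k:
        res_rss[k, cnt] = rss
        res_mask[k, cnt] = mask
        counts[k] = cnt + 1
        if counts[k] == m_k:
            worst = res_rss[k, 0]
            for t in range(1, m_k):
                if res_rss[k, t] > worst:
                    worst = res_rss[k, t]
            thr[k] = worst
        return
    worst = 0
    for t in range(1, m_k):
        if res_rss[k, t] > res_rss[k, worst]:
            worst = t
    if rss < res_rss[k, worst]:
        res_rss[k, worst] = rss
        res_mask[k, worst] = mask
        worst_rss = res_rss[k, 0]
        for t in range(1, m_k):
            if res_rss[k, t] > worst_rss:
                worst_rss = res_rss[k, t]
        thr[k] = worst_rss


@njit(cache=True)
def _sweep_drop(pool, src, dst, f):
    """Sweep pivot 0 of the (f+1)x(f+1) matrix at pool[src], dropping its
    row/column, into pool[dst] (size f x f).  The response row stays last.

    A near-zero pivot (numerically redundant column) contributes nothing:
    the child is a plain submatrix copy, the minimum-norm convention.
    """
    P = pool[src]
    d = P[0, 0]
    if abs(d) < 1e-12:
        for a in range(1, f + 1):
            for b in range(1, f + 1):
                pool[dst, a - 1, b - 1] = P[a, b]
        return
    for a in range(1, f + 1):
        pa = P[a, 0] / d
        for b in range(1, f + 1):
            pool[dst, a - 1, b - 1] = P[a, b] - pa * P[0, b]


@njit(cache=True)
def _copy_drop(pool, src, dst, f):
    P = pool[src]
    for a in range(1, f + 1):
        for b in range(1, f + 1):
            pool[dst, a - 1, b - 1] = P[a, b]


@njit(cache=True)
def _bba_walk(pool1, pool2, res_rss, res_mask, counts, thr, m, k_cap, m_k):
    """Iterative binary include/exclude walk over columns 0..m-1.

    pool1[i]: augmented Gram over active columns {i..m-1} + response,
    swept on the current subset (dead columns dropped); its [f,f] entry is
    RSS(S).  pool2[i]: same matrix additionally swept on all free columns;
    its [f,f] entry is RSS(S ∪ {i..m-1}), the monotone lower bound for the
    whole subtree.  A depth-first walk with an explicit phase stack:
    phase 0 expands the include child, phase 1 the exclude child.
    """
    st_i = np.empty(m + 2, dtype=np.int64)
    st_depth = np.empty(m + 2, dtype=np.int64)
    st_mask = np.empty(m + 2, dtype=np.uint64)
    st_phase = np.empty(m + 2, dtype=np.int64)
    top = 0
    st_i[0] = 0
    st_depth[0] = 0
    st_mask[0] = np.uint64(0)
    st_phase[0] = 0
    top = 1
    while top > 0:
        i = st_i[top - 1]
        depth = st_depth[top - 1]
        mask = st_mask[top - 1]
        phase = st_phase[top - 1]
        f = m - i
        if phase == 2 or f == 0 or depth >= k_cap:
            top -= 1
            continue
        if phase == 0:
            bound = pool2[i, f, f]
            k_hi = depth + f
            if k_hi > k_cap:
                k_hi = k_cap
            prune = True
            for k in range(depth + 1, k_hi + 1):
                if bound < thr[k]:
                    prune = False
                    break
            if prune:
                top -= 1
                continue
            # include column i: sweep it into Q1; closure (Q2) unchanged
            _sweep_drop(pool1, i, i + 1, f)
            _copy_drop(pool2, i, i + 1, f)
            rss = pool1[i + 1, f - 1, f - 1]
            if rss < 0.0:
                rss = 0.0
            bit = np.uint64(1) << np.uint64(i)
            _insert(res_rss, res_mask, counts, thr, depth + 1, rss, mask | bit, m_k)
            st_phase[top - 1] = 1
            st_i[top] = i + 1
            st_depth[top] = depth + 1
            st_mask[top] = mask | bit
            st_phase[top] = 0
            top += 1
        else:  # phase == 1
            # exclude column i: Q1 unchanged; un-sweep it from the closure
            _copy_drop(pool1, i, i + 1, f)
            _sweep_drop(pool2, i, i + 1, f)
            st_phase[top - 1] = 2
            st_i[top] = i + 1
            st_depth[top] = depth
            st_mask[top] = mask
            st_phase[top] = 0
            top += 1


@njit(cache=True)
def _bba_kernel(G, bvec, yty, m_k, k_cap):
    """Exact top-m_k subsets per size, Furnival–Wilson sweep recursion.

    Columns are assumed pre-ordered (best marginal fit first).  Returns
    per-size counts, RSS values, and subset bitmasks for sizes 1..k_cap.
    """
    m = G.shape[0]
    res_rss = np.full((k_cap + 1, m_k), np.inf)
    res_mask = np.zeros((k_cap + 1, m_k), dtype=np.uint64)
    counts = np.zeros(k_cap + 1, dtype=np.int64)
    thr = np.full(k_cap + 1, np.inf)

    # augmented Gram [[G, b], [b', yty]] with response last
    pool1 = np.empty((m + 2, m + 2, m + 2))
    pool2 = np.empty((m + 2, m + 2, m + 2))
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = G
    A[m, :m] = bvec
    A[:m, m] = bvec
    A[m, m] = yty
    pool1[0, : m + 1, : m + 1] = A
    # closure: sweep every column (in place, with singular-pivot guard)
    B = A.copy()
    for kcol in range(m):
        d = B[kcol, kcol]
        if abs(d) < 1e-12:
            continue
        for a in range(m + 1):
            if a == kcol:
                continue
            pa = B[a, kcol] / d
            for b in range(m + 1):
                if b == kcol:
                    continue
                B[a, b] -= pa * B[kcol, b]
        for a in range(m + 1):
            B[a, kcol] /= d
            B[kcol, a] /= d
        B[kcol, kcol] = -1.0 / d
    pool2[0, : m + 1, : m + 1] = B

    _bba_walk(pool1, pool2, res_rss, res_mask, counts, thr, m, k_cap, m_k)
    return counts, res_rss, res_mask


def branch_and_bound(
    target: DesignMatrix,
    pseudo_y: np.ndarray,
    w: WeightScheme,
    cfg: SearchConfig,
    columns: np.ndarray | None = None,
) -> CandidateSet:
    """Exact best-``m_k``-per-size subset search by branch and bound."""
    if columns is None:
        columns = np.arange(target.n_columns)
    cand, G, bvec, yty, base = _prepare(
        target, pseudo_y, w, columns, cfg.force_intercept
    )
    m = len(cand)
    if m > 63:
        raise ValueError("branch-and-bound supports at most 63 candidate columns")
    k_cap = min(m, cfg.s_max - base)
    # order candidates by marginal explained sum, best first (better pruning)
    marg = bvec**2 / np.maximum(np.diag(G), 1e-300)
    order = np.argsort(-marg, kind="stable")
    Gp = G[np.ix_(order, order)]
    bp = bvec[order]
    counts, res_rss, res_mask = _bba_kernel(Gp, bp, yty, cfg.m_k, max(k_cap, 1))

    by_size: dict[int, list[tuple[Subset, float]]] = {}
    if cfg.force_intercept:
        by_size[1] = [(Subset((0,)), yty)]
    for k in range(1, k_cap + 1):
        entries = []
        for t in range(counts[k]):
            mask = int(res_mask[k, t])
            pos = [j for j in range(m) if mask >> j & 1]
            orig = sorted(int(cand[order[j]]) for j in pos)
            if cfg.force_intercept:
                orig = [0] + orig
            entries.append((Subset(tuple(orig)), float(res_rss[k, t])))
        entries.sort(key=lambda e: (e[1], e[0].indices))
        if entries:
            by_size[k + base] = entries
    return CandidateSet(by_size, tuple(int(c) for c in np.sort(columns)), cfg)


# ---------------------------------------------------------------------------
# oracle / greedy strategies
# ---------------------------------------------------------------------------


def _rss_lstsq(Xw, bw):
    resid = bw - Xw @ np.linalg.lstsq(Xw, bw, rcond=None)[0]
    return float(resid @ resid)


def exhaustive_search(
    target: DesignMatrix,
    pseudo_y: np.ndarray,
    w: WeightScheme,
    cfg: SearchConfig,
    columns: np.ndarray | None = None,
) -> CandidateSet:
    """Brute-force top-``m_k`` per size (independent of the BBA path)."""
    if columns is None:
        columns = np.arange(target.n_columns)
    columns = np.asarray(columns, dtype=int)
    cand = columns[columns != 0] if cfg.force_intercept else columns
    if len(cand) > _EXHAUSTIVE_MAX_P:
        raise ValueError(
            f"exhaustive search refused for {len(cand)} columns "
            f"(> {_EXHAUSTIVE_MAX_P}); use the bba strategy"
        )
    sw = np.sqrt(w.omega)
    bw = pseudo_y * sw
    base = 1 if cfg.force_intercept else 0
    k_cap = min(len(cand), cfg.s_max - base)
    by_size: dict[int, list[tuple[Subset, float]]] = {}
    if cfg.force_intercept:
        by_size[1] = [(Subset((0,)), _rss_lstsq(sw[:, None], bw))]
    for d in range(1, k_cap + 1):
        entries = []
        for combo in itertools.combinations(cand, d):
            cols = ((0,) + combo) if cfg.force_intercept else combo
            Xw = target.columns(cols) * sw[:, None]
            entries.append((Subset(tuple(sorted(cols))), _rss_lstsq(Xw, bw)))
        entries.sort(key=lambda e: (e[1], e[0].indices))
        by_size[d + base] = entries[: cfg.m_k]
    return CandidateSet(by_size, tuple(int(c) for c in np.sort(columns)), cfg)


def _greedy(target, pseudo_y, w, cfg, columns, direction):
    columns = np.asarray(columns, dtype=int)
    cand = list(columns[columns != 0]) if cfg.force_intercept else list(columns)
    sw = np.sqrt(w.omega)
    bw = pseudo_y * sw
    base = 1 if cfg.force_intercept else 0
    k_cap = min(len(cand), cfg.s_max - base)

    def rss_of(cols):
        full = ((0,) + tuple(cols)) if cfg.force_intercept else tuple(cols)
        if not full:
            return float(bw @ bw)
        return _rss_lstsq(target.columns(full) * sw[:, None], bw)

    by_size: dict[int, list[tuple[Subset, float]]] = {}

    def record(cols):
        full = sorted(((0,) + tuple(cols)) if cfg.force_intercept else tuple(cols))
        if full:
            by_size[len(full)] = [(Subset(tuple(full)), rss_of(cols))]

    if direction == "forward":
        current: list[int] = []
        if cfg.force_intercept:
            by_size[1] = [(Subset((0,)), rss_of(()))]
        remaining = list(cand)
        while len(current) < k_cap:
            scores = [(rss_of(current + [j]), j) for j in remaining]
            best_rss, best_j = min(scores)
            current.append(best_j)
            remaining.remove(best_j)
            record(current)
    else:
        current = list(cand)[:k_cap]
        record(current)
        while len(current) > (0 if cfg.force_intercept else 1):
            scores = [
                (rss_of([c for c in current if c != j]), j) for j in current
            ]
            best_rss, drop_j = min(scores)
            current.remove(drop_j)
            if current or cfg.force_intercept:
                record(current)
            if not current:
                break
        if cfg.force_intercept and 1 not in by_size:
            by_size[1] = [(Subset((0,)), rss_of(()))]
    return CandidateSet(by_size, tuple(int(c) for c in np.sort(columns)), cfg)


def forward_search(target, pseudo_y, w, cfg, columns=None):
    """Greedy forward chain: one nested subset per size."""
    if columns is None:
        columns = np.arange(target.n_columns)
    return _greedy(target, pseudo_y, w, cfg, columns, "forward")


def backward_search(target, pseudo_y, w, cfg, columns=None):
    """Greedy backward chain from the full screened set."""
    if columns is None:
        columns = np.arange(target.n_columns)
    return _greedy(target, pseudo_y, w, cfg, columns, "backward")


def search_candidates(target, pseudo_y, w, cfg, columns=None) -> CandidateSet:
    """Dispatch on ``cfg.strategy``."""
    fn = {
        "bba": branch_and_bound,
        "exhaustive": exhaustive_search,
        "forward": forward_search,
        "backward": backward_search,
    }[cfg.strategy]
    return fn(target, pseudo_y, w, cfg, columns)
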