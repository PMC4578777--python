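"""Two-stage delayed conditional-independence inference of the initial GRN.

Stage 1 scans every ordered gene pair at every delay ``0..max_delay`` with
a Pearson correlation test on the lag-aligned sample and keeps edges whose
score -log10(p) exceeds the threshold; several delays may survive for one
pair.  Stage 2 prunes each surviving edge by partial correlation, given
every subset of up to ``max_condition`` time-shifted neighbours, in the
spirit of the PC algorithm.  Edges whose best delay is 0 are discarded at
the end, since regulation is assumed to take at least one time step.

Multiple time-series segments are handled by lagging each segment
independently and concatenating the overlapping rows ("shift and
concatenate"), so short series pooled from repeated experiments can be
used directly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grn_data import DelayedEdge, DelayedGRN, ExpressionSegments, InferenceParams

log = logging.getLogger(__name__)

_LN10 = math.log(10.0)
_MIN_VAR = 1e-12


class EmptySampleError(ValueError):
    """All segments are shorter than the largest requested lag."""


@dataclass
class ShiftedSample:
    """Lag-aligned values for a list of ``(gene, lag)`` requests.

    Column ``j`` of ``values`` holds ``x_gene(t - lag_j)`` with ``t``
    ranging over the rows each segment can support; segments contribute
    independently and their overlapping rows are stacked.
    """

    values: np.ndarray
    requests: list[tuple[int, int]]

    @property
    def n_eff(self) -> int:
        return self.values.shape[0]


def shift_and_concat(
    data: ExpressionSegments, requests: list[tuple[int, int]]
) -> ShiftedSample:
    """Build the pooled lag-aligned sample for ``(gene, lag)`` requests.

    Lags may be negative (a column *leading* the reference); internally all
    lags are offset so the smallest becomes zero, which leaves the relative
    alignment unchanged.
    """
    lags = np.array([lag for _, lag in requests], dtype=int)
    genes = [g for g, _ in requests]
    off = lags - lags.min()
    span = int(off.max())
    blocks = []
    for seg in data.segments:
        m = seg.shape[0]
        rows = m - span
        if rows <= 0:
            continue
        cols = [seg[span - off[j]: m - off[j], genes[j]] for j in range(len(genes))]
        blocks.append(np.column_stack(cols))
    if not blocks:
        raise EmptySampleError(
            f"all segments shorter than the maximum lag span {span}"
        )
    return ShiftedSample(np.vstack(blocks), list(requests))


def _score_from_r(r: np.ndarray, df: np.ndarray | int) -> np.ndarray:
    """-log10 two-sided p-value of Pearson/partial r via the t transform.

    Uses the log survival function so that near-perfect correlations do not
    underflow to p = 0.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = np.asarray(df, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r * r))
    score = np.where(
        np.isfinite(t),
        -(math.log(2.0) + stats.t.logsf(np.where(np.isfinite(t), t, 0.0), df)) / _LN10,
        np.inf,
    )
    return np.where(df > 0, score, 0.0)


def _lagged_moments(data: ExpressionSegments, d: int):
    """Pooled cross moments of ``x(t-d)`` (rows) vs ``y(t)`` (cols)."""
    n = data.n_genes
    N = 0
    sx = np.zeros(n)
    sy = np.zeros(n)
    sxx = np.zeros(n)
    syy = np.zeros(n)
    sxy = np.zeros((n, n))
    for seg in data.segments:
        m = seg.shape[0]
        if m <= d:
            continue
        a = seg[: m - d]
        b = seg[d:]
        N += m - d
        sx += a.sum(axis=0)
        sy += b.sum(axis=0)
        sxx += (a * a).sum(axis=0)
        syy += (b * b).sum(axis=0)
        sxy += a.T @ b
    return N, sx, sy, sxx, syy, sxy


def delayed_corr_test(
    data: ExpressionSegments, x: int, y: int, d: int, st: float
) -> tuple[bool, float, int]:
    """Test ``x(t-d) -> y(t)`` by Pearson correlation on the pooled sample.

    Returns ``(significant, score, effect_sign)`` with score = -log10(p).
    Degenerate (near-constant) series are reported as not significant.
    """
    sample = shift_and_concat(data, [(x, d), (y, 0)])
    a, b = sample.values[:, 0], sample.values[:, 1]
    n = sample.n_eff
    va = a.var()
    vb = b.var()
    if n < 3 or va < _MIN_VAR or vb < _MIN_VAR:
        return False, 0.0, 0
    r = float(np.cov(a, b, bias=True)[0, 1] / math.sqrt(va * vb))
    score = float(_score_from_r(np.array(r), n - 2))
    return score > st, score, int(np.sign(r)) if r != 0 else 0


def stage1_scan(data: ExpressionSegments, params: InferenceParams) -> list[DelayedEdge]:
    """Scan all ordered pairs and delays; keep significant delayed edges.

    Self-pairs are scanned only for delays >= 1 (the zero-delay
    self-correlation is trivially one).  The effect is the regression slope
    of ``y(t)`` on ``x(t-d)``, whose sign is the sign of the correlation.
    """
    n = data.n_genes
    if n == 0:
        return []
    edges: list[DelayedEdge] = []
    for d in range(params.max_delay + 1):
        N, sx, sy, sxx, syy, sxy = _lagged_moments(data, d)
        if N < 3:
            continue
        vx = sxx - sx * sx / N
        vy = syy - sy * sy / N
        cov = sxy - np.outer(sx, sy) / N
        denom = np.sqrt(np.outer(np.maximum(vx, 0.0), np.maximum(vy, 0.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > _MIN_VAR * N, cov / denom, 0.0)
            slope = np.where(vx[:, None] > _MIN_VAR * N, cov / vx[:, None], 0.0)
        ok = np.minimum.outer(vx, vy) > _MIN_VAR * N
        score = np.where(ok, _score_from_r(r, N - 2), 0.0)
        sig = score > params.st
        if d == 0:
            np.fill_diagonal(sig, False)
        for i, j in zip(*np.nonzero(sig)):
            eff = float(slope[i, j])
            if eff == 0.0:
                continue
            edges.append(DelayedEdge(int(i), int(j), d, eff, float(score[i, j])))
    edges.sort(key=lambda e: e.key)
    return edges


def _neighbour_lags(
    edge: DelayedEdge, edges: list[DelayedEdge]
) -> list[tuple[int, int]]:
    """Conditioning pool for ``edge``: genes adjacent to its endpoints.

    Each neighbour ``z`` enters with one lag, derived from the stage-1
    delay of the edge linking it to ``x`` or ``y`` so that its series is
    shifted consistently with the pair under test (lag relative to the
    target's time frame; negative lags mean the neighbour trails ``y``).
    When several relations tie a neighbour to the pair, the one with the
    highest stage-1 score wins (ties broken by smallest lag magnitude).
    """
    x, y, d = edge.src, edge.dst, edge.delay
    best: dict[int, tuple[float, int, int]] = {}
    for e in edges:
        if e.key == edge.key:
            continue
        lag: int | None = None
        z: int | None = None
        if e.dst == y and e.src not in (x, y):
            z, lag = e.src, e.delay
        elif e.dst == x and e.src not in (x, y):
            z, lag = e.src, d + e.delay
        elif e.src == x and e.dst not in (x, y):
            z, lag = e.dst, d - e.delay
        elif e.src == y and e.dst not in (x, y):
            z, lag = e.dst, -e.delay
        if z is None or lag is None:
            continue
        cand = (-(e.score or 0.0), abs(lag), lag)
        if z not in best or cand < best[z]:
            best[z] = cand
    return sorted((z, best[z][2]) for z in best)


def _partial_corr_score(values: np.ndarray) -> tuple[float, float] | None:
    """Partial correlation of columns 0,1 given the rest, with its score.

    Returns ``(r, score)`` or ``None`` when the sample is degenerate or the
    correlation matrix is singular (the test is then skipped).
    """
    n, k = values.shape
    h = k - 2
    if n < h + 3:
        return None
    sd = values.std(axis=0)
    if np.any(sd < _MIN_VAR):
        return None
    corr = np.corrcoef(values, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        return None
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        return None
    r = float(-prec[0, 1] / math.sqrt(denom))
    score = float(_score_from_r(np.array(r), n - 2 - h))
    return r, score


def stage2_prune(
    edges: list[DelayedEdge],
    data: ExpressionSegments,
    params: InferenceParams,
) -> list[DelayedEdge]:
    """Prune stage-1 edges by conditioning on growing neighbour subsets.

    For ``h = 1..max_condition`` every surviving edge is tested against
    each size-``h`` subset of its conditioning pool (deterministic
    lexicographic order); it is removed at the first non-significant
    partial correlation.  Tests whose aligned sample is too small are
    skipped.  The surviving edges keep their stage-1 delays, effects and
    scores.
    """
    current = sorted(edges, key=lambda e: e.key)
    for h in range(1, params.max_condition + 1):
        kept: list[DelayedEdge] = []
        alive = list(current)
        for idx, edge in enumerate(current):
            pool = _neighbour_lags(edge, alive)
            if len(pool) < h:
                kept.append(edge)
                continue
            removed = False
            for subset in itertools.combinations(pool, h):
                requests = [(edge.src, edge.delay), (edge.dst, 0)]
                requests += [(z, lag) for z, lag in subset]
                try:
                    sample = shift_and_concat(data, requests)
                except EmptySampleError:
                    log.debug("skipping test for %s: empty sample", edge.key)
                    continue
                res = _partial_corr_score(sample.values)
                if res is None:
                    log.debug("skipping degenerate test for %s", edge.key)
                    continue
                _, score = res
                if score <= params.st:
                    removed = True
                    break
            if not removed:
                kept.append(edge)
            else:
                alive = [e for e in alive if e.key != edge.key]
        current = kept
    return current


def infer_initial_grn(
    data: ExpressionSegments,
    params: InferenceParams,
    allowed_pairs: set[tuple[int, int]] | None = None,
) -> DelayedGRN:
    """Infer the delayed GRN among the given genes (no hidden nodes).

    ``allowed_pairs`` optionally restricts stage 1 to a set of ordered
    ``(src, dst)`` pairs (used when re-inferring the subnetwork around
    estimated hidden causes).  Edges with zero estimated delay are
    discarded after pruning.
    """
    work = data
    if params.normalize:
        pooled = data.stacked()
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd = np.where(sd < _MIN_VAR, 1.0, sd)
        work = ExpressionSegments(
            [(seg - mu) / sd for seg in data.segments], list(data.genes)
        )
    edges = stage1_scan(work, params)
    if allowed_pairs is not None:
        edges = [e for e in edges if (e.src, e.dst) in allowed_pairs]
    edges = stage2_prune(edges, work, params)
    grn = DelayedGRN(n_observed=data.n_genes, n_hidden=0, labels=list(data.genes))
    for e in edges:
        if e.delay >= 1:
            grn.add_edge(e)
    return grn
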