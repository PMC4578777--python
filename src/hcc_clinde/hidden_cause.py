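"""Detection, clustering and reconstruction of hidden common causes.

A gene whose inferred parents cannot explain its expression down to the
expected error variance sigma^2 is suspected of having an unobserved
parent: its residual variance after regressing on the (time-shifted)
parents exceeds ``(1 + rho) * sigma^2``.  Such *candidates* are greedily
clustered by maximum absolute shifted correlation — children of one hidden
hub are correlated through it — and for each multi-member cluster the
latent series is reconstructed from the rank-1 SVD of the aligned,
centred member series, extended over the unaligned prefix/suffix by least
squares, and finally shifted so that it precedes all its children in time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .clinde_engine import EmptySampleError, shift_and_concat
from .grn_data import DelayedGRN, ExpressionSegments

log = logging.getLogger(__name__)

_MIN_VAR = 1e-12


class LatentEstimationError(ValueError):
    """Raised when a cluster's latent series cannot be estimated."""


@dataclass
class CandidateSet:
    """Per-gene residual variances and the flagged candidate genes."""

    variances: np.ndarray
    sigma2: float
    tolerance: float
    flags: np.ndarray

    @property
    def candidates(self) -> list[int]:
        return [int(i) for i in np.nonzero(self.flags)[0]]


@dataclass
class HiddenCluster:
    """Candidates sharing one estimated hidden cause.

    ``shifts[k]`` is the time shift of member ``k`` relative to the cluster
    center (the first member, shift 0).  ``coeffs`` and ``series`` (one
    latent vector per segment, each of the segment's length) are filled by
    :func:`estimate_hidden_series` for clusters with more than one member.
    """

    members: list[int]
    shifts: list[int] = field(default_factory=list)
    coeffs: np.ndarray | None = None
    series: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if not self.shifts:
            self.shifts = [0] * len(self.members)
        if len(self.shifts) != len(self.members):
            raise ValueError("one shift per member required")


# -- candidate detection ---------------------------------------------------


def residual_variances(grn: DelayedGRN, data: ExpressionSegments) -> np.ndarray:
    """Residual variance of each gene regressed on its time-shifted parents.

    Ordinary least squares with an intercept; each parent series is lagged
    by the delay of its edge (one regressor per parent edge), segments
    aligned by shift-and-concatenate.  Parent-free genes report their raw
    pooled variance; so do genes whose aligned sample is too small for the
    regression.
    """
    pooled = data.stacked()
    raw = pooled.var(axis=0)
    out = np.array(raw, dtype=float)
    for j in range(data.n_genes):
        parents = [e for e in grn.edge_list() if e.dst == j]
        if not parents:
            continue
        requests = [(j, 0)] + [(e.src, e.delay) for e in parents]
        try:
            sample = shift_and_concat(data, requests)
        except EmptySampleError:
            log.warning("gene %d: no aligned rows for regression; using raw variance", j)
            continue
        vals = sample.values
        n = vals.shape[0]
        if n < len(parents) + 2:
            log.warning("gene %d: sample too small for regression; using raw variance", j)
            continue
        y = vals[:, 0]
        X = np.column_stack([np.ones(n), vals[:, 1:]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[j] = float(resid @ resid / n)
    return out


def estimate_sigma2(variances: np.ndarray) -> float:
    """Median of the per-gene residual variances.

    Robust under the assumption that only a small fraction of genes have a
    hidden parent (their variances are the outliers).
    """
    v = np.asarray(variances, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one gene")
    return float(np.median(v))


def detect_candidates(
    variances: np.ndarray, sigma2: float, tolerance: float
) -> CandidateSet:
    """Flag genes whose residual variance exceeds ``(1 + rho) * sigma^2``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    v = np.asarray(variances, dtype=float)
    flags = v > (1.0 + tolerance) * sigma2
    return CandidateSet(v, sigma2, tolerance, flags)


# -- clustering ------------------------------------------------------------


def max_abs_shifted_corr(
    data: ExpressionSegments, x: int, y: int, max_delay: int
) -> tuple[float, int]:
    """Maximum |corr(x(t), y(t + s))| over shifts ``s in -max_delay..max_delay``.

    Returns the similarity in [0, 1] and the maximising shift of ``y``
    relative to ``x`` (positive s: y lags x by s steps); ties resolved
    towards the smallest |shift|, negative shift first.  Degenerate series
    give similarity 0.
    """
    order = [0]
    for s in range(1, max_delay + 1):
        order += [-s, s]
    best_d, best_s = 0.0, 0
    for s in order:
        try:
            sample = shift_and_concat(data, [(x, s), (y, 0)])
        except EmptySampleError:
            continue
        a, b = sample.values[:, 0], sample.values[:, 1]
        va, vb = a.var(), b.var()
        if sample.n_eff < 3 or va < _MIN_VAR or vb < _MIN_VAR:
            continue
        r = abs(float(np.cov(a, b, bias=True)[0, 1] / math.sqrt(va * vb)))
        if r > best_d:
            best_d, best_s = r, s
    return best_d, best_s


def cluster_candidates(
    candidates: list[int],
    data: ExpressionSegments,
    sigma2: float,
    tolerance: float,
    max_delay: int,
) -> list[HiddenCluster]:
    """Greedy single-pass clustering of candidates by shifted correlation.

    The first candidate seeds cluster 1.  Each further candidate joins the
    cluster whose *center* (first member, never updated) it correlates with
    most, provided the similarity reaches the model-derived threshold
    ``sqrt((1 - rho0/Var(c)) (1 - rho0/Var(g)))`` with
    ``rho0 = (1 + rho) * sigma^2``; otherwise it seeds a new cluster.  If
    either variance is at or below the noise floor ``rho0`` the pair is
    non-mergeable (the theoretical threshold would be imaginary).
    """
    pooled = data.stacked()
    var = pooled.var(axis=0)
    rho0 = (1.0 + tolerance) * sigma2
    clusters: list[HiddenCluster] = []
    for g in candidates:
        if not clusters:
            clusters.append(HiddenCluster([g], [0]))
            continue
        best_j, best_d, best_shift = -1, -1.0, 0
        for j, cl in enumerate(clusters):
            d, s = max_abs_shifted_corr(data, cl.members[0], g, max_delay)
            if d > best_d:
                best_j, best_d, best_shift = j, d, s
        center = clusters[best_j].members[0]
        t1 = 1.0 - rho0 / var[center] if var[center] > 0 else -1.0
        t2 = 1.0 - rho0 / var[g] if var[g] > 0 else -1.0
        if t1 > 0 and t2 > 0 and best_d >= math.sqrt(t1 * t2):
            # store the shift in the alignment convention of the latent
            # estimator: member series enter as x'_k(t - tau_k), so a member
            # lagging its center by s has tau_k = -s
            clusters[best_j].members.append(g)
            clusters[best_j].shifts.append(-best_shift)
        else:
            clusters.append(HiddenCluster([g], [0]))
    return clusters


# -- latent series estimation ----------------------------------------------


def _center_member_blocks(
    data: ExpressionSegments, cluster: HiddenCluster
) -> list[np.ndarray]:
    """Per-segment member series, each centred within its segment."""
    blocks = []
    for seg in data.segments:
        sub = seg[:, cluster.members]
        blocks.append(sub - sub.mean(axis=0))
    return blocks


def estimate_hidden_series(
    cluster: HiddenCluster, data: ExpressionSegments, max_delay: int
) -> HiddenCluster:
    """Reconstruct the hidden series of a multi-member cluster by rank-1 SVD.

    Per segment, rows ``y_k(t) = x'_k(t - tau_k)`` over the overlap
    ``t_s..t_e`` form a matrix Y; the overlaps of all segments are stacked
    and the leading singular triple gives the coefficients ``a = sigma*u``
    (shared across segments) and the latent overlap ``h = v``.  Outside the
    overlap, ``h(t)`` is the least-squares solution
    ``sum_k a_k x'_k(t - tau_k) / sum_k a_k^2`` over the members in range.
    Finally the series is advanced by ``max_k tau_k + 1`` steps (last value
    padded with 0) so that the estimated cause precedes all its children.

    The scale and sign of ``(a, h)`` are inherently undetermined; the sign
    is fixed so that the coefficient of largest magnitude is positive.
    """
    if len(cluster.members) < 2:
        raise LatentEstimationError("latent estimation needs a cluster of size > 1")
    taus = np.array(cluster.shifts, dtype=int)
    tmax, tmin = int(taus.max()), int(taus.min())
    blocks = _center_member_blocks(data, cluster)
    overlaps = []
    spans = []
    for blk in blocks:
        m = blk.shape[0]
        t_s, t_e = 1 + tmax, m + tmin  # 1-based t with all members in range
        if t_e - t_s + 1 < 2:
            raise LatentEstimationError(
                f"segment of length {m} has overlap shorter than 2 points"
            )
        rows = [blk[t_s - 1 - tk: t_e - tk, k] for k, tk in enumerate(taus)]
        overlaps.append(np.vstack(rows))
        spans.append((t_s, t_e, m))
    Y = np.hstack(overlaps)
    u, s, vt = np.linalg.svd(Y, full_matrices=False)
    a = s[0] * u[:, 0]
    if a[np.argmax(np.abs(a))] < 0:
        a = -a
        vt = -vt
    a2 = float(a @ a)
    series: list[np.ndarray] = []
    col = 0
    for blk, (t_s, t_e, m) in zip(blocks, spans):
        width = t_e - t_s + 1
        h_over = vt[0, col: col + width]
        col += width
        # full latent time range touched by at least one member
        lo, hi = 1 + tmin, m + tmax
        h_full = np.zeros(hi - lo + 1)
        h_full[t_s - lo: t_e - lo + 1] = h_over
        for t in list(range(lo, t_s)) + list(range(t_e + 1, hi + 1)):
            num = den = 0.0
            for k, tk in enumerate(taus):
                if 1 <= t - tk <= m:
                    num += a[k] * blk[t - tk - 1, k]
                    den += a[k] * a[k]
            h_full[t - lo] = num / den if den > 0 else 0.0
        # advance so that the latent series precedes all members
        h_prime = np.zeros(m)
        for t in range(1, m):
            h_prime[t - 1] = h_full[t + tmax + 1 - lo]
        series.append(h_prime)
    cluster.coeffs = a
    cluster.series = series
    return cluster
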