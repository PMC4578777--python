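"""Ground-truth network generators and expression simulators.

Expression follows a linear vector-autoregressive model with per-edge
delays: ``x_j(t) = sum_i a_ij x_i(t - tau_ij) + e_j(t)``.  Error terms are
``sign(z) * s * |z|^alpha`` with ``z ~ N(0,1)``; ``alpha = 1`` is Gaussian
and larger ``alpha`` gives heavier tails, while ``s`` is solved
analytically so that the variance is exactly ``sigma^2``.  Networks come
in two flavours: a small star around one hidden hub (``p`` observed
parents -> hidden -> ``c`` observed children) and a large random GRN with
several hidden hubs, dedicated parent/child blocks and up to ``M0``
parents per ordinary gene, rescaled until the companion matrix of the
delayed recurrence is stable.
"""

from __future__ import annotations

import math

import numpy as np

from .grn_data import HIDDEN_PREFIX, DelayedEdge, DelayedGRN, ExpressionSegments

DEFAULT_MAX_DELAY = 4
#: spectral radius above which coefficients are rescaled, and the target
RADIUS_TRIGGER = 0.95
RADIUS_TARGET = 0.9
SEGMENT_LENGTHS = (20, 30)  # inclusive range for multi-segment simulation


def error_scale(sigma2: float, alpha: float) -> float:
    """Scale s with Var(sign(z) * s * |z|^alpha) = sigma^2 for z ~ N(0,1).

    The transformed variable is symmetric around 0, so its variance is
    ``s^2 E|z|^(2 alpha)`` with
    ``E|z|^(2 alpha) = 2^alpha Gamma(alpha + 1/2) / sqrt(pi)``.
    """
    if sigma2 <= 0 or alpha <= 0:
        raise ValueError("sigma2 and alpha must be positive")
    second_moment = 2.0**alpha * math.gamma(alpha + 0.5) / math.sqrt(math.pi)
    return math.sqrt(sigma2 / second_moment)


def gen_error_series(
    count: int, m: int, sigma2: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """An ``m x count`` matrix of i.i.d. error terms with variance sigma^2."""
    z = rng.standard_normal((m, count))
    s = error_scale(sigma2, alpha)
    return np.sign(z) * s * np.abs(z) ** alpha


def _random_effect(rng: np.random.Generator) -> float:
    """Signed coefficient: sign uniform on {-1, 1}, magnitude on (0.5, 1.5)."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * rng.uniform(0.5, 1.5)


def _random_delay(rng: np.random.Generator, max_delay: int) -> int:
    return int(rng.integers(1, max_delay + 1))


def _permute_observed(grn: DelayedGRN, rng: np.random.Generator) -> DelayedGRN:
    """Randomly relabel the observed node indices (hidden nodes stay put)."""
    perm = rng.permutation(grn.n_observed)
    mapping = {old: int(new) for old, new in enumerate(perm)}
    for h in range(grn.n_observed, grn.n_nodes):
        mapping[h] = h
    out = DelayedGRN(
        n_observed=grn.n_observed, n_hidden=grn.n_hidden, labels=list(grn.labels)
    )
    for e in grn.edge_list():
        out.add_edge(
            DelayedEdge(mapping[e.src], mapping[e.dst], e.delay, e.effect, e.score)
        )
    return out


def gen_small_hidden_grn(
    p: int, c: int, max_delay: int = DEFAULT_MAX_DELAY, rng: np.random.Generator | None = None
) -> DelayedGRN:
    """Star GRN: ``p`` observed parents -> one hidden hub -> ``c`` children."""
    if c < 2:
        raise ValueError("a hidden node needs at least 2 children")
    if p < 0:
        raise ValueError("p must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n = p + c
    grn = DelayedGRN(n_observed=n, n_hidden=1)
    hidden = n
    for i in range(p):
        grn.add_edge(
            DelayedEdge(i, hidden, _random_delay(rng, max_delay), _random_effect(rng))
        )
    for j in range(p, n):
        grn.add_edge(
            DelayedEdge(hidden, j, _random_delay(rng, max_delay), _random_effect(rng))
        )
    return _permute_observed(grn, rng)


def gen_fallback_nonhidden_grn(
    p: int, c: int, max_delay: int = DEFAULT_MAX_DELAY, rng: np.random.Generator | None = None
) -> DelayedGRN:
    """All-observed star: a middle node with ``p`` parents and ``c - 1`` children."""
    rng = np.random.default_rng() if rng is None else rng
    n = p + c
    grn = DelayedGRN(n_observed=n, n_hidden=0)
    middle = p
    for i in range(p):
        grn.add_edge(
            DelayedEdge(i, middle, _random_delay(rng, max_delay), _random_effect(rng))
        )
    for j in range(p + 1, n):
        grn.add_edge(
            DelayedEdge(middle, j, _random_delay(rng, max_delay), _random_effect(rng))
        )
    return _permute_observed(grn, rng)


def gen_confusing_nonhidden_grn(
    p: int,
    c: int,
    incomplete_data: ExpressionSegments,
    rng: np.random.Generator,
    max_delay: int = DEFAULT_MAX_DELAY,
    st: float = 2.0,
) -> DelayedGRN:
    """Truth network for the no-hidden control case.

    The network inferred by the plain two-stage engine from data that *did*
    have a hidden hub is deliberately misleading (none of its links are
    real); re-used as a ground truth with every node observed, it probes
    the pipeline's behaviour when nothing is actually hidden.  If that
    network is empty, an all-observed star with ``p`` parents and ``c - 1``
    children is generated instead.
    """
    from .clinde_engine import infer_initial_grn
    from .grn_data import InferenceParams

    inferred = infer_initial_grn(
        incomplete_data, InferenceParams(st=st, max_delay=max_delay)
    )
    if inferred.edges:
        return DelayedGRN(
            n_observed=inferred.n_observed,
            n_hidden=0,
            edges={
                k: DelayedEdge(e.src, e.dst, e.delay, e.effect, None)
                for k, e in inferred.edges.items()
            },
            labels=list(inferred.labels),
        )
    return gen_fallback_nonhidden_grn(p, c, max_delay, rng)


def gen_large_grn(
    n: int,
    n_h: int,
    max_parents: int = 4,
    max_delay: int = DEFAULT_MAX_DELAY,
    rng: np.random.Generator | None = None,
    stabilized: bool = True,
) -> DelayedGRN:
    """Large random GRN with ``n_h`` hidden hubs over dedicated node blocks.

    Hidden-node parent counts are drawn from {0,1,2,3} and child counts
    from {2,3,4,5}, with ``floor(n_h / 4)`` nodes pinned to each value and
    the remainder drawn uniformly.  The observed genes are partitioned into
    ordinary genes, parents-of-hidden and children-of-hidden; ordinary
    genes draw up to ``max_parents`` parents from all observed genes,
    parents-of-hidden exclude children-of-hidden as sources, and
    children-of-hidden have exactly their hidden parent.  Coefficients are
    rescaled for stability and observed indices are permuted.
    """
    rng = np.random.default_rng() if rng is None else rng
    quota = n_h // 4
    parent_counts: list[int] = []
    child_counts: list[int] = []
    for i in (0, 1, 2, 3):
        parent_counts += [i] * quota
    parent_counts += [int(rng.integers(0, 4)) for _ in range(n_h - len(parent_counts))]
    for i in (2, 3, 4, 5):
        child_counts += [i] * quota
    child_counts += [int(rng.integers(2, 6)) for _ in range(n_h - len(child_counts))]

    n_p = sum(parent_counts)
    n_c = sum(child_counts)
    n_o = n - n_p - n_c
    if n_o <= 0:
        raise ValueError(
            f"n={n} too small for n_h={n_h}: parent/child blocks need {n_p + n_c} genes"
        )

    grn = DelayedGRN(n_observed=n, n_hidden=n_h)

    def link(src: int, dst: int) -> None:
        grn.add_edge(
            DelayedEdge(src, dst, _random_delay(rng, max_delay), _random_effect(rng))
        )

    # ordinary genes: up to max_parents parents from any observed gene
    for i in range(n_o):
        k = int(rng.integers(0, max_parents + 1))
        for src in rng.choice(n, size=k, replace=False):
            link(int(src), i)
    # parents-of-hidden: parents drawn outside the children-of-hidden block
    for i in range(n_o, n_o + n_p):
        k = int(rng.integers(0, max_parents + 1))
        for src in rng.choice(n - n_c, size=k, replace=False):
            link(int(src), i)
    # hidden wiring over the dedicated, disjoint blocks
    pp = n_o
    cc = n_o + n_p
    for h in range(n_h):
        hid = n + h
        for _ in range(parent_counts[h]):
            link(pp, hid)
            pp += 1
        for _ in range(child_counts[h]):
            link(hid, cc)
            cc += 1
    if stabilized:
        grn = stabilize(grn, max_delay=max_delay)
    return _permute_observed(grn, rng)


def companion_spectral_radius(grn: DelayedGRN, max_delay: int | None = None) -> float:
    """Spectral radius of the companion matrix of the delayed recurrence."""
    n = grn.n_nodes
    tau0 = max_delay or max((e.delay for e in grn.edge_list()), default=1)
    A = [np.zeros((n, n)) for _ in range(tau0)]
    for e in grn.edge_list():
        A[e.delay - 1][e.dst, e.src] += e.effect
    top = np.hstack(A)
    lower = np.hstack([np.eye(n * (tau0 - 1)), np.zeros((n * (tau0 - 1), n))])
    comp = np.vstack([top, lower]) if tau0 > 1 else top
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def stabilize(
    grn: DelayedGRN,
    max_delay: int | None = None,
    trigger: float = RADIUS_TRIGGER,
    target: float = RADIUS_TARGET,
) -> DelayedGRN:
    """Uniformly shrink coefficients until the recurrence is stable.

    If the companion spectral radius is below ``trigger`` the network is
    returned unchanged; otherwise all coefficients are multiplied by a
    common factor until the radius drops to ``target`` or below.
    """
    radius = companion_spectral_radius(grn, max_delay)
    if radius < trigger:
        return grn
    out = grn.copy()
    for _ in range(200):
        factor = target / radius * 0.999
        out = DelayedGRN(
            n_observed=out.n_observed,
            n_hidden=out.n_hidden,
            edges={
                k: DelayedEdge(e.src, e.dst, e.delay, e.effect * factor, e.score)
                for k, e in out.edges.items()
            },
            labels=list(out.labels),
        )
        radius = companion_spectral_radius(out, max_delay)
        if radius <= target:
            return out
    raise RuntimeError("failed to stabilize network")


def simulate_expression(
    grn: DelayedGRN,
    m: int,
    sigma2: float,
    alpha: float,
    rng: np.random.Generator,
    max_delay: int = DEFAULT_MAX_DELAY,
    hetero_delta2: float | None = None,
    complete: bool = False,
) -> ExpressionSegments:
    """Simulate one segment of ``m`` time points from the delayed VAR model.

    Burn-in values ``x_j(t) = e_j(t) ~ N(0,1)`` seed the first ``max_delay``
    steps.  With ``hetero_delta2`` set, each gene gets its own error
    variance ``max(0.1, z)`` with ``z ~ N(2, delta^2)`` instead of the
    shared ``sigma2``.  ``complete=True`` also emits the hidden columns
    (after the observed ones).
    """
    n = grn.n_nodes
    tau0 = max_delay
    if hetero_delta2 is not None:
        sig2 = np.maximum(0.1, rng.normal(2.0, math.sqrt(hetero_delta2), size=n))
    else:
        sig2 = np.full(n, float(sigma2))
    x = np.zeros((tau0 + m, n))
    x[:tau0] = rng.standard_normal((tau0, n))
    noise = np.column_stack(
        [gen_error_series(1, m, sig2[j], alpha, rng)[:, 0] for j in range(n)]
    )
    in_edges: list[list[tuple[int, int, float]]] = [[] for _ in range(n)]
    for e in grn.edge_list():
        in_edges[e.dst].append((e.src, e.delay, e.effect))
    for t in range(tau0, tau0 + m):
        row = noise[t - tau0].copy()
        for j in range(n):
            for src, delay, eff in in_edges[j]:
                row[j] += eff * x[t - delay, src]
        x[t] = row
    full = x[tau0:]
    if complete:
        return ExpressionSegments([full], list(grn.labels))
    return ExpressionSegments(
        [full[:, : grn.n_observed]], list(grn.labels[: grn.n_observed])
    )


def simulate_segments(
    grn: DelayedGRN,
    K: int,
    sigma2: float,
    alpha: float,
    rng: np.random.Generator,
    max_delay: int = DEFAULT_MAX_DELAY,
    hetero_delta2: float | None = None,
    complete: bool = False,
) -> ExpressionSegments:
    """``K`` independently simulated segments with lengths uniform in 20..30."""
    if K < 1:
        raise ValueError("K must be >= 1")
    lo, hi = SEGMENT_LENGTHS
    segs: list[np.ndarray] = []
    genes: list[str] | None = None
    for _ in range(K):
        length = int(rng.integers(lo, hi + 1))
        one = simulate_expression(
            grn, length, sigma2, alpha, rng,
            max_delay=max_delay, hetero_delta2=hetero_delta2, complete=complete,
        )
        segs.append(one.segments[0])
        genes = one.genes
    assert genes is not None
    return ExpressionSegments(segs, genes)
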