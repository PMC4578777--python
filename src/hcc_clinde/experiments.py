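"""Replicated benchmark harness over the synthetic study conditions.

Each *cell* fixes a network family (small star with one hidden hub, the
matching no-hidden control, or a large multi-hub GRN), the noise model
(sigma^2, alpha, optionally heterogeneous variances) and the data budget
(m time points in one segment, or K short segments).  Per replicate three
methods are scored against the ground truth:

* ``complete`` — the plain two-stage engine on *all* columns, hidden ones
  included (an upper-bound reference);
* ``hidden``   — the full pipeline with hidden-cause recovery on the
  observed columns only;
* ``hiddenCL`` — the plain engine on the observed columns (the initial
  GRN, i.e. what one gets by ignoring hidden causes).

Medians of the per-replicate F-scores summarise a cell, and a one-sided
Wilcoxon signed-rank test compares ``hidden`` against ``hiddenCL``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clinde_engine import infer_initial_grn
from .evaluation import EvalReport, evaluate
from .grn_data import DelayedGRN, ExpressionSegments, InferenceParams
from .reinference import hcc_clinde
from .synthetic_gen import (
    DEFAULT_MAX_DELAY,
    gen_confusing_nonhidden_grn,
    gen_large_grn,
    gen_small_hidden_grn,
    simulate_expression,
    simulate_segments,
)

log = logging.getLogger(__name__)

SMALL_SIM_POINTS = 200  # one long simulation per small replicate; prefixes sliced
LARGE_SIM_POINTS = 800

CASES = ("small-hidden", "small-nonhidden", "large")
METHODS = ("complete", "hidden", "hiddenCL")


@dataclass
class ExperimentCell:
    """One parameter setting of the synthetic benchmark grid."""

    case: str = "small-hidden"
    p: int = 0
    c: int = 2
    n: int = 50
    sigma2: float = 2.0
    alpha: float = 0.5
    delta2: float | None = None
    m: int | None = 200
    K: int | None = None
    st: float = 2.0
    max_delay: int = DEFAULT_MAX_DELAY
    max_parents: int = 4

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"unknown case {self.case!r}")
        if (self.m is None) == (self.K is None):
            raise ValueError("set exactly one of m (one segment) or K (segments)")

    @property
    def n_hidden(self) -> int:
        return math.ceil(self.n / 10)

    @property
    def sigma2_known(self) -> bool:
        return self.case.startswith("small")


@dataclass
class CellResult:
    cell: ExperimentCell
    reports: dict[str, list[EvalReport]]
    failures: int = 0
    seeds: list[int] = field(default_factory=list)


def _simulate(cell: ExperimentCell, grn: DelayedGRN, rng: np.random.Generator,
              complete: bool) -> ExpressionSegments:
    if cell.K is not None:
        return simulate_segments(
            grn, cell.K, cell.sigma2, cell.alpha, rng,
            max_delay=cell.max_delay, hetero_delta2=cell.delta2, complete=complete,
        )
    sim_m = SMALL_SIM_POINTS if cell.case.startswith("small") else LARGE_SIM_POINTS
    data = simulate_expression(
        grn, sim_m, cell.sigma2, cell.alpha, rng,
        max_delay=cell.max_delay, hetero_delta2=cell.delta2, complete=complete,
    )
    return data.prefix(cell.m)


def _truth_and_data(
    cell: ExperimentCell, rng: np.random.Generator
) -> tuple[DelayedGRN, ExpressionSegments]:
    """Ground-truth network and *complete* data for one replicate."""
    if cell.case == "small-hidden":
        grn = gen_small_hidden_grn(cell.p, cell.c, cell.max_delay, rng)
    elif cell.case == "small-nonhidden":
        # the control truth is the engine's own (wrong) read of a hidden-hub
        # replicate; its data is discarded afterwards
        probe = gen_small_hidden_grn(cell.p, cell.c, cell.max_delay, rng)
        probe_data = simulate_expression(
            probe, SMALL_SIM_POINTS, cell.sigma2, cell.alpha, rng,
            max_delay=cell.max_delay,
        )
        grn = gen_confusing_nonhidden_grn(
            cell.p, cell.c, probe_data, rng, max_delay=cell.max_delay
        )
    else:
        grn = gen_large_grn(
            cell.n, cell.n_hidden, cell.max_parents, cell.max_delay, rng
        )
    data = _simulate(cell, grn, rng, complete=True)
    return grn, data


def run_replicate(
    cell: ExperimentCell,
    rng: np.random.Generator,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, EvalReport]:
    """Generate one replicate and score the requested methods against truth."""
    grn, complete_data = _truth_and_data(cell, rng)
    observed = complete_data.select(
        range(grn.n_observed), grn.labels[: grn.n_observed]
    )
    params = InferenceParams(
        st=cell.st,
        max_delay=cell.max_delay,
        sigma2=cell.sigma2 if cell.sigma2_known else None,
    )
    out: dict[str, EvalReport] = {}
    if "hidden" in methods or "hiddenCL" in methods:
        final, details = hcc_clinde(observed, params, return_details=True)
        if "hidden" in methods:
            out["hidden"] = evaluate(grn, final, cell.max_delay)
        if "hiddenCL" in methods:
            out["hiddenCL"] = evaluate(grn, details.initial, cell.max_delay)
    if "complete" in methods:
        pred = infer_initial_grn(complete_data, params)
        out["complete"] = evaluate(grn, pred, cell.max_delay)
    return out


def run_cell(
    cell: ExperimentCell,
    replicates: int,
    seed: int,
    methods: tuple[str, ...] = METHODS,
) -> CellResult:
    """Run all replicates of a cell; failed replicates are logged and skipped."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(replicates)
    reports: dict[str, list[EvalReport]] = {m: [] for m in methods}
    failures = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            rep = run_replicate(cell, rng, methods)
        except Exception:  # noqa: BLE001 - a replicate must not kill the cell
            log.exception("replicate %d of %s failed", i, cell)
            failures += 1
            continue
        for m in methods:
            reports[m].append(rep[m])
    return CellResult(cell=cell, reports=reports, failures=failures)


def median_f(reports: list[EvalReport], aspect: str = "effects") -> float:
    if not reports:
        return float("nan")
    return float(np.median([r.scores[aspect].f_score for r in reports]))


def summarize(result: CellResult) -> dict:
    """Median R/P/F table per method/aspect plus the hidden-vs-hiddenCL test."""
    table: dict[str, dict[str, dict[str, float]]] = {}
    for method, reps in result.reports.items():
        table[method] = {}
        for aspect in ("links", "delays", "effects"):
            table[method][aspect] = {
                "recall": float(np.median([r.scores[aspect].recall for r in reps])) if reps else float("nan"),
                "precision": float(np.median([r.scores[aspect].precision for r in reps])) if reps else float("nan"),
                "f": median_f(reps, aspect),
            }
    out = {"medians": table, "failures": result.failures}
    if "hidden" in result.reports and "hiddenCL" in result.reports:
        out["wilcoxon_hidden_gt_hiddenCL"] = wilcoxon_paired(
            [r.effects.f_score for r in result.reports["hidden"]],
            [r.effects.f_score for r in result.reports["hiddenCL"]],
        )
    return out


def wilcoxon_paired(x: list[float], y: list[float]) -> float:
    """One-sided signed-rank p-value for median(x) > median(y).

    Zero differences are dropped (standard convention); the exact null
    distribution is used for up to 25 non-zero pairs, the normal
    approximation above that.  All-zero differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            x, y, alternative="greater", zero_method="wilcox", method=method
        )
    except ValueError:
        res = stats.wilcoxon(x, y, alternative="greater", zero_method="wilcox")
    return float(res.pvalue)
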