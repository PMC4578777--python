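"""Re-inference of the subnetwork around estimated hidden causes.

Once latent series have been reconstructed, the causal neighbourhood of
each hidden cause is re-estimated by running the two-stage engine on the
candidates, their initial-GRN parents and the latent series, restricted to
the only structurally admissible link types: parent -> hidden,
parent -> candidate and hidden -> candidate.  The fragment then replaces
the in-links of the candidates in the initial GRN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clinde_engine import infer_initial_grn
from .grn_data import (
    HIDDEN_PREFIX,
    DelayedEdge,
    DelayedGRN,
    ExpressionSegments,
    InferenceParams,
)
from .hidden_cause import (
    CandidateSet,
    HiddenCluster,
    LatentEstimationError,
    cluster_candidates,
    detect_candidates,
    estimate_hidden_series,
    estimate_sigma2,
    residual_variances,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineDetails:
    """Intermediate products of a full pipeline run, for inspection."""

    initial: DelayedGRN
    variances: np.ndarray | None = None
    sigma2: float | None = None
    candidates: list[int] = field(default_factory=list)
    clusters: list[HiddenCluster] = field(default_factory=list)
    fragment: DelayedGRN | None = None
    exit_reason: str | None = None


def infer_hidden_subnetwork(
    clusters: list[HiddenCluster],
    candidates: list[int],
    initial: DelayedGRN,
    data: ExpressionSegments,
    params: InferenceParams,
) -> DelayedGRN:
    """Infer the restricted subnetwork around the estimated hidden causes.

    Variables are the candidates, their parents in the initial GRN and one
    latent series per estimated cluster; stage 1 only scans the admissible
    ordered pairs.  The returned fragment is a network over the observed
    genes of ``data`` plus ``len(clusters)`` hidden nodes, containing only
    parent->hidden, parent->candidate and hidden->candidate links.
    """
    emitted = [c for c in clusters if c.series is not None]
    if len(emitted) != len(clusters):
        raise ValueError("all clusters passed for re-inference need estimated series")
    cand_set = set(candidates)
    parent_set: set[int] = set()
    for e in initial.edge_list():
        if e.dst in cand_set and e.src not in cand_set:
            parent_set.add(e.src)
    if not clusters or not candidates:
        return DelayedGRN(n_observed=data.n_genes, n_hidden=len(clusters), labels=None)

    n_obs = data.n_genes
    k = len(clusters)
    latent_blocks = [
        np.column_stack([cl.series[s] for cl in clusters])
        for s in range(len(data.segments))
    ]
    hidden_names = [f"{HIDDEN_PREFIX}{i}" for i in range(k)]
    aug = data.with_columns(latent_blocks, hidden_names)

    hidden_ids = set(range(n_obs, n_obs + k))
    allowed: set[tuple[int, int]] = set()
    for p in parent_set:
        for h in hidden_ids:
            allowed.add((p, h))
        for c in cand_set:
            allowed.add((p, c))
    for h in hidden_ids:
        for c in cand_set:
            allowed.add((h, c))

    sub = infer_initial_grn(aug, params, allowed_pairs=allowed)
    fragment = DelayedGRN(
        n_observed=n_obs, n_hidden=k, labels=list(data.genes) + hidden_names
    )
    for e in sub.edge_list():
        fragment.add_edge(e)
    return fragment


def merge_networks(
    initial: DelayedGRN,
    fragment: DelayedGRN,
    candidates: list[int],
    stripped: set[int] | None = None,
) -> DelayedGRN:
    """Replace candidate in-links of the initial GRN by the fragment.

    ``stripped`` is the set of candidates whose initial in-links are
    removed unconditionally (the members of emitted clusters); any other
    candidate loses its in-links only if the fragment supplies replacements,
    so that singleton candidates are not orphaned.
    """
    if stripped is None:
        stripped = set(candidates)
    frag_targets = {e.dst for e in fragment.edge_list()}
    drop_into = set(stripped) | (set(candidates) & frag_targets)
    final = DelayedGRN(
        n_observed=initial.n_observed,
        n_hidden=fragment.n_hidden,
        labels=list(initial.labels[: initial.n_observed])
        + list(fragment.labels[fragment.n_observed:]),
    )
    for e in initial.edge_list():
        if e.dst not in drop_into:
            final.add_edge(e)
    for e in fragment.edge_list():
        final.add_edge(e)
    return final


def hcc_clinde(
    data: ExpressionSegments,
    params: InferenceParams,
    return_details: bool = False,
) -> DelayedGRN | tuple[DelayedGRN, PipelineDetails]:
    """Full pipeline: initial GRN, hidden-cause detection, re-inference.

    Steps: (1) infer the initial GRN over the observed genes; (2) compute
    per-gene residual variances and take sigma^2 as given or as their
    median; (3) flag candidates; (4) greedily cluster them; (5) estimate
    one latent series per multi-member cluster; (6) re-infer the restricted
    subnetwork and merge.  Early exits (no candidates, only singleton
    clusters, no estimable cluster) return the initial GRN unchanged.
    """
    initial = infer_initial_grn(data, params)
    details = PipelineDetails(initial=initial)

    variances = residual_variances(initial, data)
    sigma2 = params.sigma2 if params.sigma2 is not None else estimate_sigma2(variances)
    details.variances = variances
    details.sigma2 = sigma2

    cand: CandidateSet = detect_candidates(variances, sigma2, params.tolerance)
    details.candidates = cand.candidates
    if not cand.candidates:
        details.exit_reason = "no candidates"
        log.info("no candidate genes: returning the initial GRN")
        return (initial, details) if return_details else initial

    clusters = cluster_candidates(
        cand.candidates, data, sigma2, params.tolerance, params.max_delay
    )
    details.clusters = clusters
    multi = [c for c in clusters if len(c.members) > 1]
    if not multi:
        details.exit_reason = "all clusters singleton"
        log.info("all candidate clusters are singletons: returning the initial GRN")
        return (initial, details) if return_details else initial

    estimated: list[HiddenCluster] = []
    for cl in multi:
        try:
            estimated.append(estimate_hidden_series(cl, data, params.max_delay))
        except LatentEstimationError as exc:
            log.warning("dropping cluster %s: %s", cl.members, exc)
    if not estimated:
        details.exit_reason = "no estimable cluster"
        log.info("no cluster allowed latent estimation: returning the initial GRN")
        return (initial, details) if return_details else initial

    fragment = infer_hidden_subnetwork(
        estimated, cand.candidates, initial, data, params
    )
    details.fragment = fragment
    stripped = {g for cl in estimated for g in cl.members}
    final = merge_networks(initial, fragment, cand.candidates, stripped=stripped)
    return (final, details) if return_details else final
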