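"""Scoring of a predicted network against a known truth.

Three nested aspects are scored: *Links* (ordered gene pair), *Delays*
(link plus exact delay) and *Effects* (link plus effect sign), each with
recall, precision and F-score.  Because a hidden node is never observed,
its links are only identified up to a joint sign flip and a compensating
delay shift (adding d to in-link delays while subtracting d from out-link
delays leaves the observable behaviour unchanged), so predicted hidden
nodes are first aligned to true hidden nodes over these equivalence
transformations before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grn_data import DelayedEdge, DelayedGRN

ASPECTS = ("links", "delays", "effects")


@dataclass(frozen=True)
class AspectScore:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0


@dataclass(frozen=True)
class HiddenAlignment:
    """Mapping of one predicted hidden node onto a true hidden node."""

    true_node: int
    delay_shift: int
    flipped: bool


@dataclass
class EvalReport:
    scores: dict[str, AspectScore]
    alignment: dict[int, HiddenAlignment] = field(default_factory=dict)

    @property
    def links(self) -> AspectScore:
        return self.scores["links"]

    @property
    def delays(self) -> AspectScore:
        return self.scores["delays"]

    @property
    def effects(self) -> AspectScore:
        return self.scores["effects"]


def _sign(x: float) -> int:
    return 1 if x > 0 else -1


def _edge_keys(grn: DelayedGRN, aspect: str) -> set[tuple]:
    labels = grn.labels
    if aspect == "links":
        return {(labels[e.src], labels[e.dst]) for e in grn.edge_list()}
    if aspect == "delays":
        return {(labels[e.src], labels[e.dst], e.delay) for e in grn.edge_list()}
    if aspect == "effects":
        return {(labels[e.src], labels[e.dst], _sign(e.effect)) for e in grn.edge_list()}
    raise ValueError(f"unknown aspect {aspect!r}")


def match_edges(truth: DelayedGRN, pred: DelayedGRN, aspect: str) -> AspectScore:
    """Count TP/FP/FN for one aspect; nodes are matched by label.

    Duplicate predictions of the same key (e.g. two delays for one pair in
    the Links aspect) collapse to one.
    """
    t = _edge_keys(truth, aspect)
    p = _edge_keys(pred, aspect)
    return AspectScore(tp=len(t & p), fp=len(p - t), fn=len(t - p))


def _links_of_hidden(grn: DelayedGRN, h: int) -> list[tuple[bool, str, int, int]]:
    """(is_parent_link, observed label, delay, sign) for node ``h``'s links
    to/from observed genes."""
    out = []
    for e in grn.edge_list():
        if e.dst == h and not grn.is_hidden(e.src):
            out.append((True, grn.labels[e.src], e.delay, _sign(e.effect)))
        elif e.src == h and not grn.is_hidden(e.dst):
            out.append((False, grn.labels[e.dst], e.delay, _sign(e.effect)))
    return out


def align_hidden(
    truth: DelayedGRN, pred: DelayedGRN, max_delay: int
) -> dict[int, HiddenAlignment]:
    """Align each predicted hidden node to the best-matching true one.

    Every predicted hidden node is aligned independently: over each true
    hidden node, each delay shift ``d`` (in-link delays + d, out-link
    delays - d, all shifted delays kept within ``[1, 2*max_delay]``) and
    each sign flip, the primary score is the number of matched links plus
    matched shifted delays.  Ties are broken by more matched effect signs,
    then the lowest true node index, the smallest |d| and no-flip.
    Predicted hidden nodes with no positive score stay unaligned (all
    their links count as false positives downstream).
    """
    truth_links = {
        h: _links_of_hidden(truth, h)
        for h in range(truth.n_observed, truth.n_nodes)
    }
    out: dict[int, HiddenAlignment] = {}
    for ph in range(pred.n_observed, pred.n_nodes):
        plinks = _links_of_hidden(pred, ph)
        if not plinks:
            continue
        best = None  # (-score, -signs, true index, |d|, flip, d)
        for th, tlinks in truth_links.items():
            tset = {(isp, lab) for isp, lab, _, _ in tlinks}
            tdel = {(isp, lab, dly) for isp, lab, dly, _ in tlinks}
            tsgn = {(isp, lab, sg) for isp, lab, _, sg in tlinks}
            for d in range(-2 * max_delay, 2 * max_delay + 1):
                shifted = []
                valid = True
                for isp, lab, dly, sg in plinks:
                    nd = dly + d if isp else dly - d
                    if not (1 <= nd <= 2 * max_delay):
                        valid = False
                        break
                    shifted.append((isp, lab, nd, sg))
                if not valid:
                    continue
                for flip in (False, True):
                    links = sum((isp, lab) in tset for isp, lab, _, _ in shifted)
                    delays = sum((isp, lab, nd) in tdel for isp, lab, nd, _ in shifted)
                    signs = sum(
                        (isp, lab, -sg if flip else sg) in tsgn
                        for isp, lab, _, sg in shifted
                    )
                    score = links + delays
                    if score == 0:
                        continue
                    cand = (-score, -signs, th, abs(d), flip, d)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            out[ph] = HiddenAlignment(true_node=best[2], delay_shift=best[5], flipped=best[4])
    return out


def _apply_alignment(
    truth: DelayedGRN, pred: DelayedGRN, alignment: dict[int, HiddenAlignment]
) -> DelayedGRN:
    """Rewrite predicted hidden links per the alignment.

    Aligned hidden nodes take the label of their true counterpart with
    shifted delays and (optionally) flipped signs; unaligned ones keep a
    fresh label that matches nothing in the truth.
    """
    labels = list(pred.labels)
    for ph, al in alignment.items():
        labels[ph] = truth.labels[al.true_node]
    for ph in range(pred.n_observed, pred.n_nodes):
        if ph not in alignment:
            labels[ph] = f"__unmatched_{pred.labels[ph]}"
    out = DelayedGRN(
        n_observed=pred.n_observed, n_hidden=pred.n_hidden, labels=labels
    )
    for e in pred.edge_list():
        delay, effect = e.delay, e.effect
        if e.dst in alignment:
            al = alignment[e.dst]
            delay += al.delay_shift
            if al.flipped:
                effect = -effect
        elif e.src in alignment:
            al = alignment[e.src]
            delay -= al.delay_shift
            if al.flipped:
                effect = -effect
        out.edges[(e.src, e.dst, delay)] = DelayedEdge(e.src, e.dst, delay, effect, e.score)
    return out


def evaluate(truth: DelayedGRN, pred: DelayedGRN, max_delay: int = 4) -> EvalReport:
    """Align predicted hidden nodes, then score Links/Delays/Effects."""
    alignment = align_hidden(truth, pred, max_delay)
    aligned = _apply_alignment(truth, pred, alignment)
    scores = {a: match_edges(truth, aligned, a) for a in ASPECTS}
    return EvalReport(scores=scores, alignment=alignment)
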