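"""Core domain types and file I/O for delayed gene regulatory networks.

A GRN here is a signed, delay-labelled directed multigraph over observed
genes plus zero or more *hidden* nodes (unobserved common causes).  Edges
are keyed by ``(src, dst, delay)`` so that several delays may coexist for
the same ordered gene pair, which the inference engine can produce
transiently.  Expression data is a list of equidistant time-series
*segments* (rows = time points, columns = genes) sharing one gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: label prefix reserved for hidden nodes in files and generated networks
HIDDEN_PREFIX = "HID"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True, order=True)
class DelayedEdge:
    """A directed regulatory edge ``src -> dst`` with a time delay.

    ``effect`` is the signed regulatory strength (negative = repression),
    ``score`` the -log10 p-value of the test that accepted the edge
    (``None`` for ground-truth networks).
    """

    src: int
    dst: int
    delay: int
    effect: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect) or self.effect == 0.0:
            raise ValueError(f"edge effect must be finite and non-zero, got {self.effect}")
        if self.delay < 0:
            raise ValueError(f"edge delay must be >= 0, got {self.delay}")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.src, self.dst, self.delay)


@dataclass
class DelayedGRN:
    """Delayed GRN over ``n_observed`` observed and ``n_hidden`` hidden nodes.

    Node indices are 0-based; hidden nodes occupy the indices
    ``n_observed .. n_observed + n_hidden - 1``.  ``labels`` holds one name
    per node (hidden names carry :data:`HIDDEN_PREFIX`).
    """

    n_observed: int
    n_hidden: int = 0
    edges: dict[tuple[int, int, int], DelayedEdge] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [f"G{i}" for i in range(self.n_observed)] + [
                f"{HIDDEN_PREFIX}{i}" for i in range(self.n_hidden)
            ]
        if len(self.labels) != self.n_nodes:
            raise ValueError("labels must cover all nodes")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.n_observed + self.n_hidden

    def is_hidden(self, node: int) -> bool:
        return node >= self.n_observed

    def add_edge(self, edge: DelayedEdge) -> None:
        self.edges[edge.key] = edge

    def edge_list(self) -> list[DelayedEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def parents_of(self, node: int) -> list[DelayedEdge]:
        return [e for e in self.edge_list() if e.dst == node]

    def children_of(self, node: int) -> list[DelayedEdge]:
        return [e for e in self.edge_list() if e.src == node]

    def copy(self) -> "DelayedGRN":
        return DelayedGRN(
            n_observed=self.n_observed,
            n_hidden=self.n_hidden,
            edges=dict(self.edges),
            labels=list(self.labels),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DelayedGRN):
            return NotImplemented
        return (
            self.n_observed == other.n_observed
            and self.n_hidden == other.n_hidden
            and self.labels == other.labels
            and self.edges == other.edges
        )

    def relabelled(self, labels: Sequence[str]) -> "DelayedGRN":
        g = self.copy()
        g.labels = list(labels)
        if len(g.labels) != g.n_nodes:
            raise ValueError("labels must cover all nodes")
        return g


@dataclass
class ExpressionSegments:
    """One or more equidistant expression time-series over a shared gene set."""

    segments: list[np.ndarray]
    genes: list[str]

    def __post_init__(self) -> None:
        for k, seg in enumerate(self.segments):
            seg = np.asarray(seg, dtype=float)
            if seg.ndim != 2 or seg.shape[1] != len(self.genes):
                raise ValueError(f"segment {k} has shape {seg.shape}, expected (*, {len(self.genes)})")
            if seg.shape[0] < 2:
                raise ValueError(f"segment {k} has fewer than 2 time points")
            if not np.all(np.isfinite(seg)):
                raise ValueError(f"segment {k} contains missing or non-finite values")
            self.segments[k] = seg

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def lengths(self) -> list[int]:
        return [seg.shape[0] for seg in self.segments]

    @property
    def total_points(self) -> int:
        return sum(self.lengths)

    def stacked(self) -> np.ndarray:
        return np.vstack(self.segments)

    def select(self, columns: Sequence[int], genes: Sequence[str] | None = None) -> "ExpressionSegments":
        cols = list(columns)
        names = list(genes) if genes is not None else [self.genes[c] for c in cols]
        return ExpressionSegments([seg[:, cols] for seg in self.segments], names)

    def with_columns(self, extra: list[np.ndarray], names: Sequence[str]) -> "ExpressionSegments":
        """Append extra per-segment columns (e.g. reconstructed latent series)."""
        if len(extra) != len(self.segments):
            raise ValueError("one extra block per segment required")
        segs = []
        for seg, blk in zip(self.segments, extra):
            blk = np.asarray(blk, dtype=float)
            if blk.ndim == 1:
                blk = blk[:, None]
            if blk.shape[0] != seg.shape[0]:
                raise ValueError("extra columns must match segment length")
            segs.append(np.hstack([seg, blk]))
        return ExpressionSegments(segs, list(self.genes) + list(names))

    def prefix(self, m: int) -> "ExpressionSegments":
        """First ``m`` time points of every segment."""
        return ExpressionSegments([seg[:m] for seg in self.segments], list(self.genes))


@dataclass
class InferenceParams:
    """Tuning knobs of the inference pipeline.

    ``st`` is the threshold on -log10(p) above which a (conditional)
    correlation is significant; ``max_delay`` the largest lag scanned;
    ``max_condition`` the largest conditioning-set size in the pruning
    stage; ``tolerance`` the relative excess over the expected error
    variance that flags a gene as having a hidden parent.  ``sigma2`` is
    the known error variance, or ``None`` to estimate it as the median of
    the per-gene residual variances.
    """

    st: float = 2.0
    max_delay: int = 4
    max_condition: int = 2
    tolerance: float = 0.1
    sigma2: float | None = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.max_delay < 1:
            raise ValueError("max_delay must be >= 1")
        if self.max_condition < 0:
            raise ValueError("max_condition must be >= 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive when given")

    def with_st(self, st: float) -> "InferenceParams":
        return replace(self, st=st)


# -- expression I/O --------------------------------------------------------


def read_segments(paths: Iterable[str | Path]) -> ExpressionSegments:
    """Load one TSV expression file per segment (header = gene names)."""
    paths = list(paths)
    if not paths:
        raise FormatError("no expression files given")
    segs: list[np.ndarray] = []
    genes: list[str] | None = None
    for path in paths:
        try:
            df = pd.read_csv(path, sep="\t")
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
        if genes is None:
            genes = [str(c) for c in df.columns]
        elif [str(c) for c in df.columns] != genes:
            raise FormatError(f"{path}: gene columns differ from first file")
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
        if np.isnan(mat).any():
            raise FormatError(f"{path}: missing values are not supported")
        segs.append(mat)
    assert genes is not None
    return ExpressionSegments(segs, genes)


def write_segments(data: ExpressionSegments, paths: Iterable[str | Path]) -> None:
    paths = list(paths)
    if len(paths) != len(data.segments):
        raise ValueError("need one output path per segment")
    for path, seg in zip(paths, data.segments):
        pd.DataFrame(seg, columns=data.genes).to_csv(path, sep="\t", index=False)


# -- network I/O -----------------------------------------------------------

_GRN_HEADER = "src\tdst\tdelay\teffect\tscore"


def write_grn(grn: DelayedGRN, path: str | Path) -> None:
    """Write a network as a TSV edge list with node lists in comments."""
    obs = grn.labels[: grn.n_observed]
    hid = grn.labels[grn.n_observed:]
    lines = [
        "# observed: " + "\t".join(obs),
        "# hidden: " + "\t".join(hid),
        _GRN_HEADER,
    ]
    for e in grn.edge_list():
        score = "NA" if e.score is None else repr(float(e.score))
        lines.append(f"{grn.labels[e.src]}\t{grn.labels[e.dst]}\t{e.delay}\t{e.effect!r}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_grn(path: str | Path, allow_zero_delay: bool = False) -> DelayedGRN:
    """Read a network written by :func:`write_grn`.

    Final networks must have strictly positive delays; pass
    ``allow_zero_delay=True`` only for intermediate inspection files.
    """
    obs: list[str] = []
    hid: list[str] = []
    edges: list[tuple[str, str, int, float, float | None]] = []
    seen_header = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("observed:"):
                rest = body[len("observed:"):].strip()
                obs = rest.split("\t") if rest else []
            elif body.startswith("hidden:"):
                rest = body[len("hidden:"):].strip()
                hid = rest.split("\t") if rest else []
            continue
        if not seen_header:
            if line != _GRN_HEADER:
                raise FormatError(f"{path}:{lineno}: expected header '{_GRN_HEADER}'")
            seen_header = True
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            delay = int(parts[2])
            effect = float(parts[3])
            score = None if parts[4] == "NA" else float(parts[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if delay < 1 and not allow_zero_delay:
            raise FormatError(f"{path}:{lineno}: delay must be >= 1 in a final network")
        edges.append((parts[0], parts[1], delay, effect, score))
    if not seen_header:
        raise FormatError(f"{path}: missing edge-list header")
    labels = obs + hid
    index = {name: i for i, name in enumerate(labels)}
    grn = DelayedGRN(n_observed=len(obs), n_hidden=len(hid), labels=labels)
    for lineno_src, lineno_dst, delay, effect, score in edges:
        for name in (lineno_src, lineno_dst):
            if name not in index:
                raise FormatError(f"{path}: edge references unknown node '{name}'")
        grn.add_edge(DelayedEdge(index[lineno_src], index[lineno_dst], delay, effect, score))
    return grn


# -- structural validation -------------------------------------------------


def validate_hidden_structure(grn: DelayedGRN) -> list[str]:
    """Check the structural assumptions on hidden nodes; returns violations.

    The model assumes: no hidden-hidden edges; every hidden node has at
    least two observed children; a gene with a hidden parent has no other
    parent; children of a hidden node are not linked to each other; and
    0 <= n_hidden < n_observed.
    """
    bad: list[str] = []
    if not (0 <= grn.n_hidden < grn.n_observed):
        bad.append(f"need 0 <= n_hidden < n_observed, got {grn.n_hidden} vs {grn.n_observed}")
    edges = grn.edge_list()
    for e in edges:
        if grn.is_hidden(e.src) and grn.is_hidden(e.dst):
            bad.append(f"hidden-hidden edge {grn.labels[e.src]} -> {grn.labels[e.dst]}")
    for h in range(grn.n_observed, grn.n_nodes):
        children = {e.dst for e in edges if e.src == h and not grn.is_hidden(e.dst)}
        if len(children) < 2:
            bad.append(f"hidden node {grn.labels[h]} has {len(children)} observed children (< 2)")
        for e in edges:
            if e.src in children and e.dst in children:
                bad.append(
                    f"children {grn.labels[e.src]} and {grn.labels[e.dst]} of "
                    f"{grn.labels[h]} are linked"
                )
    for j in range(grn.n_observed):
        parents = {e.src for e in edges if e.dst == j}
        hidden_parents = {p for p in parents if grn.is_hidden(p)}
        if hidden_parents and len(parents) > 1:
            bad.append(f"gene {grn.labels[j]} has a hidden parent plus other parents")
    return bad
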