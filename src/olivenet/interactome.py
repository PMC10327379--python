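"""Weighted protein-protein interaction networks and their propagation operators.

The interactome is an undirected graph whose nodes are proteins (opaque
string identifiers) and whose edges carry integer confidence scores in
[0, 999], following the STRING convention.  Networks are read from a
STRING-dialect edge list, thresholded on the confidence score, and turned
into a column-stochastic transition operator for random-walk propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MAX_SCORE = 999


class EdgeListParseError(ValueError):
    """A malformed row in an edge-list or target-table file."""


@dataclass(frozen=True)
class Interactome:
    """An undirected, confidence-weighted protein interaction network.

    Nodes are ordered lexicographically; edges are canonicalised so that
    each unordered pair appears once with its maximum observed score and
    self-loops are excluded.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "Interactome":
        """Build a network from raw edge tuples.

        Duplicate edges (in either orientation) are merged keeping the
        maximum score; self-loops are dropped with a warning but their
        node is retained.
        """
        merged: dict[tuple[str, str], int] = {}
        nodes: set[str] = set(extra_nodes)
        for a, b, score in edges:
            if not 0 <= score <= MAX_SCORE:
                raise ValueError(
                    f"edge score {score} for ({a}, {b}) outside [0, {MAX_SCORE}]"
                )
            nodes.add(a)
            nodes.add(b)
            if a == b:
                logger.warning("dropping self-loop on node %r", a)
                continue
            key = (a, b) if a < b else (b, a)
            prev = merged.get(key)
            if prev is None or score > prev:
                merged[key] = score
        node_ids = tuple(sorted(nodes))
        index = {n: i for i, n in enumerate(node_ids)}
        edge_tuples = tuple(
            (a, b, s) for (a, b), s in sorted(merged.items())
        )
        return cls(node_ids=node_ids, edges=edge_tuples, index=index)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class TransitionOperator:
    """Column-stochastic weighted adjacency for random-walk propagation.

    ``matrix[i, j]`` is the probability of stepping to node ``i`` from
    node ``j``.  Columns of dangling nodes (no retained edge) are all
    zero; propagation redirects their outflow to the restart vector.
    """

    matrix: sp.csr_matrix = field(repr=False)
    dangling: np.ndarray = field(repr=False)  # boolean mask, length N
    node_ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)
    threshold: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def read_edge_list(path: str | Path, dialect: str = "string_tsv") -> Interactome:
    """Read a STRING-dialect edge list (protein1, protein2, combined_score).

    Fields are tab- or whitespace-separated; an optional header line
    starting with ``protein1`` is skipped.  Raises
    :class:`EdgeListParseError` with the offending line number on
    malformed rows and on empty files.
    """
    if dialect != "string_tsv":
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    path = Path(path)
    edges: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("protein1"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}"
                )
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: score {parts[2]!r} is not an integer"
                ) from exc
            edges.append((parts[0], parts[1], score))
    if not edges:
        raise EdgeListParseError(f"{path}: no edges found")
    return Interactome.from_edges(edges)


def write_edge_list(net: Interactome, path: str | Path) -> None:
    """Write a network back to the STRING dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in net.edges:
            fh.write(f"{a}\t{b}\t{s}\n")


def apply_threshold(net: Interactome, min_score: int) -> Interactome:
    """Keep edges with score >= ``min_score``; the node set is unchanged.

    Nodes that lose all their edges stay in the universe (they become
    dangling in the transition operator).
    """
    if not 0 <= min_score <= MAX_SCORE + 1:
        raise ValueError(f"min_score {min_score} outside [0, {MAX_SCORE + 1}]")
    kept = tuple(e for e in net.edges if e[2] >= min_score)
    return Interactome(node_ids=net.node_ids, edges=kept, index=net.index)


def build_transition(
    net: Interactome, weighting: str = "raw", threshold: int | None = None
) -> TransitionOperator:
    """Column-normalise the weighted adjacency into a transition operator.

    With ``weighting='raw'`` the confidence scores are used as edge
    weights; with ``'binary'`` every retained edge has weight 1.  Entry
    (i, j) is score(i, j) / sum_k score(k, j), so each non-dangling
    column sums to one.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if weighting not in ("raw", "binary"):
        raise ValueError(f"weighting must be 'raw' or 'binary', got {weighting!r}")
    n = net.n_nodes
    if net.n_edges:
        ii = np.empty(2 * net.n_edges, dtype=np.int64)
        jj = np.empty(2 * net.n_edges, dtype=np.int64)
        ww = np.empty(2 * net.n_edges, dtype=np.float64)
        for k, (a, b, s) in enumerate(net.edges):
            ia, ib = net.index[a], net.index[b]
            w = 1.0 if weighting == "binary" else float(s)
            ii[2 * k], jj[2 * k], ww[2 * k] = ia, ib, w
            ii[2 * k + 1], jj[2 * k + 1], ww[2 * k + 1] = ib, ia, w
        adj = sp.csc_matrix((ww, (ii, jj)), shape=(n, n))
    else:
        adj = sp.csc_matrix((n, n), dtype=np.float64)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    dangling = col_sums == 0
    scale = np.where(dangling, 1.0, col_sums)
    matrix = (adj @ sp.diags(1.0 / scale)).tocsr()
    return TransitionOperator(
        matrix=matrix,
        dangling=dangling,
        node_ids=net.node_ids,
        index=net.index,
        threshold=threshold,
    )
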