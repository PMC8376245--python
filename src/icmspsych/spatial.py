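"""Spatial clustering statistics for categorical labels on electrode arrays.

The statistic follows the LISA (local indicators of spatial association)
tradition adapted to categorical marks on a lattice: the *adjacency
fraction* is the proportion of tested electrodes that have at least one
lattice-adjacent tested electrode sharing their category.  Significance
is assessed with a Monte-Carlo permutation null — the observed label
multiset is redistributed uniformly at random over the same tested
locations across both arrays jointly, preserving category counts — and
reported as a pseudo p-value: the fraction of permutations whose
adjacency fraction is greater than or equal to the observed one.

A full exact-enumeration null is provided for small problems and serves
as the oracle for the Monte-Carlo estimator.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .core_io import ArrayGridMap, ValidationError

#: Rook = 4-neighbourhood (edge-sharing); queen = 8-neighbourhood.
SCHEMES = {
    "rook": ((1, 0), (-1, 0), (0, 1), (0, -1)),
    "queen": ((1, 0), (-1, 0), (0, 1), (0, -1),
              (1, 1), (1, -1), (-1, 1), (-1, -1)),
}


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected adjacency graph over tested lattice sites.

    Nodes are (array, row, col) coordinates; edges join lattice-adjacent
    tested sites within the same array (arrays are physically disjoint, so
    no cross-array edges exist).
    """

    nodes: tuple[tuple[int, int, int], ...]
    edges: np.ndarray  # (m, 2) int array of node indices, i < j

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def node_index(self) -> dict[tuple[int, int, int], int]:
        return {site: i for i, site in enumerate(self.nodes)}


def build_adjacency(grid: ArrayGridMap, scheme: str = "rook") -> AdjacencyGraph:
    """Adjacency graph over the tested sites of a grid map.

    Unwired and wired-but-untested sites contribute neither nodes nor
    edges.  Sites whose lattice neighbours are all untested remain in the
    graph with degree zero.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use 'rook' or 'queen'")
    offsets = SCHEMES[scheme]
    sites = grid.tested_sites()
    index = {s: i for i, s in enumerate(sites)}
    edges = []
    for (a, r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((a, r + dr, c + dc))
            if j is not None and i < j:
                edges.append((i, j))
    edge_arr = (np.array(sorted(edges), dtype=int) if edges
                else np.zeros((0, 2), dtype=int))
    return AdjacencyGraph(nodes=tuple(sites), edges=edge_arr)


def graph_labels(grid: ArrayGridMap, graph: AdjacencyGraph) -> np.ndarray:
    """Category labels aligned with ``graph.nodes`` (error if any missing)."""
    labels = []
    for site in graph.nodes:
        cat = grid.category[site]
        if cat is None or cat == "untested":
            raise ValidationError(f"site {site} in graph has no category label")
        labels.append(cat)
    return np.array(labels, dtype=object)


# --------------------------------------------------------------------------
# Adjacency fraction
# --------------------------------------------------------------------------

def _encode(labels: Sequence) -> np.ndarray:
    uniq = {lab: k for k, lab in enumerate(dict.fromkeys(labels))}
    return np.array([uniq[lab] for lab in labels], dtype=np.int64)


def _fractions(label_matrix: np.ndarray, graph: AdjacencyGraph,
               denominator: str) -> np.ndarray:
    """Adjacency fraction for each row of an (s, n) label matrix."""
    s, n = label_matrix.shape
    deg = graph.degrees
    if denominator == "with_neighbor":
        denom = int((deg > 0).sum())
    elif denominator == "all_tested":
        denom = n
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0 or len(graph.edges) == 0:
        raise ValidationError("graph has no edges; adjacency fraction undefined")
    has_same = np.zeros((s, n), dtype=bool)
    for i, j in graph.edges:
        same = label_matrix[:, i] == label_matrix[:, j]
        has_same[:, i] |= same
        has_same[:, j] |= same
    active = deg > 0
    return has_same[:, active].sum(axis=1) / denom


def adjacency_fraction(labels, graph: AdjacencyGraph,
                       denominator: str = "with_neighbor") -> float:
    """Fraction of tested electrodes with a same-category tested neighbour.

    Numerator: electrodes having at least one adjacent electrode of the
    same category.  Denominator (``'with_neighbor'``, default): electrodes
    having at least one adjacent tested electrode — degree-zero sites are
    excluded from both sides, making the statistic a proportion in [0, 1].
    The alternative reading ``'all_tested'`` divides by every tested
    electrode instead.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_nodes:
        raise ValidationError(
            f"{len(labels)} labels for {graph.n_nodes} graph nodes")
    enc = _encode(labels)
    return float(_fractions(enc[None, :], graph, denominator)[0])


# --------------------------------------------------------------------------
# Monte-Carlo permutation test
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_fraction: float
    null_fractions: np.ndarray
    pseudo_p: float
    n_sims: int
    seed: int | None

    def __post_init__(self) -> None:
        assert len(self.null_fractions) == self.n_sims


def permutation_test(
    labels,
    graph: AdjacencyGraph,
    n_sims: int = 100_000,
    seed: int | None = None,
    denominator: str = "with_neighbor",
    chunk_size: int = 20_000,
) -> PermutationResult:
    """Monte-Carlo permutation test of the adjacency fraction.

    Every simulation redistributes the observed label multiset uniformly
    at random over all tested sites (across both arrays jointly),
    preserving the number of electrodes in each category.  The pseudo
    p-value is the plain proportion of simulations whose fraction is
    greater than or equal to the observed one (ties count toward the
    tail; no +1 correction).
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    labels = np.asarray(labels, dtype=object)
    enc = _encode(labels)
    observed = float(_fractions(enc[None, :], graph, denominator)[0])

    rng = np.random.default_rng(seed)
    nulls = np.empty(n_sims, dtype=float)
    done = 0
    while done < n_sims:
        s = min(chunk_size, n_sims - done)
        mat = rng.permuted(np.tile(enc, (s, 1)), axis=1)
        nulls[done:done + s] = _fractions(mat, graph, denominator)
        done += s
    pseudo_p = float(np.count_nonzero(nulls >= observed - 1e-12) / n_sims)
    return PermutationResult(observed_fraction=observed, null_fractions=nulls,
                             pseudo_p=pseudo_p, n_sims=n_sims, seed=seed)


# --------------------------------------------------------------------------
# Exact enumeration null (oracle for the Monte-Carlo test)
# --------------------------------------------------------------------------

@dataclass
class ExactNull:
    """Exact permutation-null distribution of the adjacency fraction."""

    values: np.ndarray        # sorted distinct fraction values
    probabilities: np.ndarray  # matching exact probabilities (sum to 1)
    n_arrangements: int

    def tail_probability(self, observed: float) -> float:
        """Exact P(fraction >= observed) under the permutation null."""
        mask = self.values >= observed - 1e-12
        return float(self.probabilities[mask].sum())


def _n_arrangements(counts: Mapping) -> int:
    total = sum(counts.values())
    n = math.factorial(total)
    for c in counts.values():
        n //= math.factorial(c)
    return n


def exact_null(labels, graph: AdjacencyGraph,
               denominator: str = "with_neighbor",
               max_arrangements: int = 10 ** 6) -> ExactNull:
    """Enumerate every arrangement of the label multiset over the sites.

    Computes the exact null distribution of the adjacency fraction for
    fixed category counts.  The number of distinct arrangements (a
    multinomial coefficient) must not exceed ``max_arrangements``; larger
    problems should use :func:`permutation_test`.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_nodes:
        raise ValidationError(
            f"{len(labels)} labels for {graph.n_nodes} graph nodes")
    enc = _encode(labels)
    counts: dict[int, int] = {}
    for v in enc:
        counts[int(v)] = counts.get(int(v), 0) + 1
    n_arr = _n_arrangements(counts)
    if n_arr > max_arrangements:
        raise ValidationError(
            f"{n_arr} arrangements exceed the enumeration bound "
            f"{max_arrangements}; use the Monte-Carlo permutation test")

    arrangements = np.array(list(multiset_permutations(enc.tolist())),
                            dtype=np.int64)
    fracs = _fractions(arrangements, graph, denominator)
    values, counts_per = np.unique(np.round(fracs, 12), return_counts=True)
    probs = counts_per / n_arr
    return ExactNull(values=values, probabilities=probs, n_arrangements=n_arr)
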