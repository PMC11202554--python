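"""Nei's (1972) standard genetic distance and UPGMA dendrograms.

The distance between two populations is D = -ln I with the genetic
identity I = Jxy / sqrt(Jx * Jy), where Jxy, Jx and Jy accumulate
sum_alleles(x * y), sum(x^2) and sum(y^2) over all loci callable in both
populations.  UPGMA (average linkage) then builds an ultrametric
dendrogram whose node heights are half the average pairwise distance, so
branch lengths stay in distance units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger("snppanel")

FreqTable = Mapping[str, Mapping[str, tuple[Mapping[str, float], int]]]


def nei_distance(freqs_by_population: FreqTable) -> tuple[list[str], np.ndarray]:
    """Pairwise Nei (1972) standard genetic distances.

    ``freqs_by_population`` maps population -> locus -> (allele
    frequencies, n called); loci uncallable (n = 0) in either member of a
    pair are excluded pairwise.  A pair sharing no alleles anywhere has
    identity 0 and distance +inf (reported with a warning).
    """
    labels = list(freqs_by_population)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            fi = freqs_by_population[labels[i]]
            fj = freqs_by_population[labels[j]]
            jxy = jx = jy = 0.0
            shared_loci = 0
            for locus in fi:
                if locus not in fj:
                    continue
                (px, nx), (py, ny) = fi[locus], fj[locus]
                if nx == 0 or ny == 0:
                    continue
                shared_loci += 1
                alleles = set(px) | set(py)
                for a in alleles:
                    x, y = px.get(a, 0.0), py.get(a, 0.0)
                    jxy += x * y
                    jx += x * x
                    jy += y * y
            if shared_loci == 0:
                raise ValueError(f"no shared callable loci for {labels[i]}/{labels[j]}")
            identity = jxy / math.sqrt(jx * jy)
            if identity <= 0:
                log.warning("populations %s/%s share no alleles; distance is infinite",
                            labels[i], labels[j])
                dist = math.inf
            else:
                dist = max(0.0, -math.log(min(identity, 1.0)))
            d[i, j] = d[j, i] = dist
    return labels, d


@dataclass(frozen=True)
class TreeNode:
    """A rooted ultrametric dendrogram node.

    ``height`` is the node's distance from the leaf level (leaves are at
    height 0); a child's branch length is ``parent.height - child.height``.
    """

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out += c.leaves()
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(c._newick_inner(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.10g}"

    def max_root_to_leaf(self) -> float:
        return self.height

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """All root-to-leaf path lengths equal within tolerance."""
        depths: list[float] = []

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths.append(acc + node.height)
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self, 0.0)
        return max(depths) - min(depths) <= tol


def upgma(d: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Node height is half the average inter-cluster distance.  When several
    pairs tie at the minimum distance, the pair whose (lexicographically
    smallest leaf of each cluster) sorts first is joined, making the
    topology deterministic.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances; cannot cluster")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    clusters: dict[int, TreeNode] = {
        i: TreeNode(0.0, name=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    minleaf = {i: lab for i, lab in enumerate(labels)}
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best_pair = None
        best = (math.inf, "", "")
        for pair, val in dist.items():
            i, j = sorted(pair, key=lambda k: minleaf[k])
            key = (val, minleaf[i], minleaf[j])
            if key < best:
                best = key
                best_pair = (i, j)
        i, j = best_pair
        height = best[0] / 2.0
        node = TreeNode(height, children=(clusters[i], clusters[j]))
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dist.pop(frozenset((i, j)))
        clusters[next_id] = node
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        minleaf[next_id] = min(minleaf.pop(i), minleaf.pop(j))
        del clusters[i], clusters[j]
        next_id += 1
    return clusters.popitem()[1]


@dataclass
class DistanceTree:
    """Pairwise Nei distances plus their UPGMA dendrogram."""

    labels: list[str]
    d: np.ndarray
    tree: TreeNode

    @classmethod
    def from_frequencies(cls, freqs_by_population: FreqTable) -> "DistanceTree":
        labels, d = nei_distance(freqs_by_population)
        return cls(labels, d, upgma(d, labels))
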