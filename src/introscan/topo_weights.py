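"""Topology weighting over group-labelled trees.

For k groups there are (2k - 5)!! distinct unrooted bifurcating
topologies (15 for k = 5). Given a window tree with several tips per
group, the weight of each topology is the fraction of one-tip-per-group
subsamples whose induced subtree matches it — computed exhaustively when
the number of combinations is small (default <= 10,000) and by seeded
Monte-Carlo subsampling otherwise. A subsample that induces an
unresolved (polytomous) subtree contributes fractional weight split
equally among the compatible binary topologies.

A neighbor-joining window-tree builder on allele-sharing distances is
included so the weighting can be exercised end-to-end on synthetic
genotypes.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "Topology",
    "TopologySet",
    "TopologyWeightRow",
    "enumerate_topologies",
    "weight_tree",
    "nj_window_tree",
]


@dataclass(frozen=True)
class Topology:
    """One unrooted bifurcating topology over the group labels.

    ``splits`` is the set of non-trivial bipartitions, each represented
    by the frozenset of groups on the side *not* containing the reference
    (first) group; ``newick`` is the canonical string form.
    """

    newick: str
    splits: frozenset[frozenset[str]]


@dataclass
class TopologySet:
    labels: tuple[str, ...]
    topologies: list[Topology]

    def __len__(self) -> int:
        return len(self.topologies)

    def __iter__(self):
        return iter(self.topologies)

    def index_of(self, splits: frozenset[frozenset[str]]) -> int:
        return self._lookup[splits]

    def __post_init__(self) -> None:
        self._lookup = {t.splits: i for i, t in enumerate(self.topologies)}


@dataclass
class TopologyWeightRow:
    weights: np.ndarray
    n_combinations: int
    exact: bool


def _rooted_trees(labels: Sequence[str]):
    """All rooted binary tree shapes on the given labels (nested tuples)."""
    if len(labels) == 1:
        return [labels[0]]

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert_everywhere(left, leaf):
                yield (t, right)
            for t in insert_everywhere(right, leaf):
                yield (left, t)

    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [t for base in trees for t in insert_everywhere(base, leaf)]
    return trees


def _canonical(tree) -> str:
    if isinstance(tree, str):
        return tree
    parts = sorted(_canonical(c) for c in tree)
    return "(" + ",".join(parts) + ")"


def _clades(tree, out: list[frozenset]) -> frozenset:
    if isinstance(tree, str):
        return frozenset([tree])
    left = _clades(tree[0], out)
    right = _clades(tree[1], out)
    clade = left | right
    out.append(clade)
    return clade


def enumerate_topologies(groups: int | Sequence[str]) -> TopologySet:
    """Enumerate all unrooted binary topologies on k >= 3 group labels.

    An unrooted topology on k labels corresponds to a rooted one on the
    last k - 1 labels (rooted at the edge leading to the first label),
    which gives the double-factorial count (2k - 5)!!.
    """
    labels = (
        tuple(f"G{i + 1}" for i in range(groups))
        if isinstance(groups, int)
        else tuple(groups)
    )
    k = len(labels)
    if k < 3:
        raise ValueError("need at least 3 groups")
    if len(set(labels)) != k:
        raise ValueError("group labels must be unique")
    ref, rest = labels[0], labels[1:]
    seen: dict[str, Topology] = {}
    for tree in _rooted_trees(rest):
        # rooted tree on k-1 labels; its top-level children plus ref form
        # the unrooted trifurcating newick
        if isinstance(tree, str):
            newick = f"({ref},{tree});"
        else:
            parts = sorted([_canonical(tree[0]), _canonical(tree[1])])
            newick = f"({ref},{parts[0]},{parts[1]});"
        clades: list[frozenset] = []
        _clades(tree, clades)
        splits = frozenset(c for c in clades if 2 <= len(c) <= k - 2)
        if newick not in seen:
            seen[newick] = Topology(newick=newick, splits=splits)
    topologies = [seen[n] for n in sorted(seen)]
    expected = int(np.prod(np.arange(2 * k - 5, 0, -2)))
    if len(topologies) != expected:  # pragma: no cover - internal check
        raise AssertionError(
            f"enumerated {len(topologies)} topologies, expected {expected}"
        )
    return TopologySet(labels=labels, topologies=topologies)


def _edge_leafsets(tree) -> list[set[str]]:
    """Leaf-name sets below each internal edge of a dendropy tree."""
    sets = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sets.append({leaf.taxon.label for leaf in node.leaf_iter()})
    return sets


def _as_dendropy(tree):
    import dendropy

    if isinstance(tree, str):
        return dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True
        )
    return tree


def weight_tree(
    tree,
    groups: Mapping[str, str],
    topologies: TopologySet,
    max_exact: int = 10_000,
    n_samples: int = 1000,
    seed: int = 0,
) -> TopologyWeightRow:
    """Weight one group-labelled tree across the topology set.

    ``tree`` is a newick string or dendropy Tree; ``groups`` maps tip
    label to group label. Every group must have at least one tip and
    every tip must be mapped. The returned weights are proportions and
    sum to 1.
    """
    tree = _as_dendropy(tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unknown = [t for t in tips if t not in groups]
    if unknown:
        raise ValueError(f"tips with unknown group: {sorted(unknown)}")
    group_tips: dict[str, list[str]] = {g: [] for g in topologies.labels}
    for tip in tips:
        g = groups[tip]
        if g in group_tips:
            group_tips[g].append(tip)
    empty = [g for g, lst in group_tips.items() if not lst]
    if empty:
        raise ValueError(f"groups without tips in tree: {empty}")

    leafsets = _edge_leafsets(tree)
    k = len(topologies.labels)
    ref = topologies.labels[0]
    all_groups = frozenset(topologies.labels)

    def induced_splits(combo: dict[str, str]) -> frozenset[frozenset[str]]:
        chosen = set(combo.values())
        tip_group = {tip: g for g, tip in combo.items()}
        splits = set()
        for below in leafsets:
            side = frozenset(tip_group[t] for t in (below & chosen))
            if 2 <= len(side) <= k - 2:
                if ref in side:
                    side = all_groups - side
                splits.add(side)
        return frozenset(splits)

    weights = np.zeros(len(topologies))
    tip_lists = [group_tips[g] for g in topologies.labels]
    n_comb = int(np.prod([len(lst) for lst in tip_lists]))
    exact = n_comb <= max_exact
    if exact:
        combos = product(*tip_lists)
        n_used = n_comb
    else:
        rng = np.random.default_rng(seed)
        combos = (
            tuple(lst[rng.integers(len(lst))] for lst in tip_lists)
            for _ in range(n_samples)
        )
        n_used = n_samples

    for chosen in combos:
        combo = dict(zip(topologies.labels, chosen))
        splits = induced_splits(combo)
        if len(splits) == k - 3:
            weights[topologies.index_of(splits)] += 1.0
        else:  # unresolved: share among compatible binary topologies
            compatible = [
                i for i, t in enumerate(topologies) if splits <= t.splits
            ]
            for i in compatible:
                weights[i] += 1.0 / len(compatible)
    return TopologyWeightRow(
        weights=weights / n_used, n_combinations=n_comb, exact=exact
    )


def nj_window_tree(
    gm: GenotypeMatrix, window: tuple[str, int, int] | None = None
) -> str:
    """Neighbor-joining tree (newick) on pairwise allele-sharing distances.

    The distance between two samples is the mean over shared non-missing
    sites of |dosage_i - dosage_j| / 2. ``window`` restricts sites to the
    half-open span (chrom, start, end). Deterministic given its input;
    an all-identical sample set yields a star-like tree and a warning.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if window is not None:
        chrom, start, end = window
        mask = (
            (gm.sites["chrom"] == chrom)
            & (gm.sites["pos"] >= start)
            & (gm.sites["pos"] < end)
        ).to_numpy()
        gm = gm.take_sites(mask)
    if gm.n_samples < 4:
        raise ValueError("neighbor joining needs >= 4 samples")
    if gm.n_sites < 1:
        raise ValueError("no variant sites in window")
    n = gm.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.isfinite(gm.dosage[i]) & np.isfinite(gm.dosage[j])
            if not shared.any():
                raise ValueError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no "
                    "called sites"
                )
            d = np.abs(gm.dosage[i, shared] - gm.dosage[j, shared]).mean() / 2.0
            dist[i, j] = dist[j, i] = d
    if not dist.any():
        warnings.warn("all samples identical: star tree", stacklevel=2)
    dm = DistanceMatrix(dist, ids=list(gm.samples))
    tree = nj(dm)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
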