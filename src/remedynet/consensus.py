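"""Cross-threshold consensus: co-occurrence matrix, ordering, core extraction.

For each threshold the best partition is computed once; the consensus step
then counts, for every ingredient pair, the number of thresholds at which
the pair shared a community.  Pairs with count equal to the number of
thresholds T are *core pairs* — combinations robust to the entire sweep.
Connected components of the core-pair graph form *core groups*.

A node isolated at some threshold sits in a singleton community there, so
its pair counts are capped below T; "together at every threshold" is
therefore a real constraint, not a bookkeeping artifact.

The matrix is rendered as a grayscale heat map after a (reverse)
Cuthill-McKee reordering of the binarized pattern, which concentrates
nonzeros near the diagonal and makes nested block structure visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import reverse_cuthill_mckee

from .commdetect import Partition
from .errors import ValidationError


@dataclass
class CooccurrenceMatrix:
    """Symmetric integer matrix of community co-occurrence counts.

    ``counts[i, j]`` = number of thresholds at which ingredients i and j
    were assigned to the same community; the diagonal records presence
    (= T, since isolated nodes are retained as singletons).
    """

    order: List[str]
    counts: np.ndarray
    n_thresholds: int

    def __post_init__(self):
        c, T = self.counts, self.n_thresholds
        if c.shape != (len(self.order), len(self.order)):
            raise ValidationError("counts shape does not match node order")
        if not np.array_equal(c, c.T):
            raise ValidationError("co-occurrence matrix must be symmetric")
        if c.min() < 0 or c.max() > T:
            raise ValidationError("counts must lie in [0, T]")

    def pair_count(self, u: str, v: str) -> int:
        i, j = self.order.index(u), self.order.index(v)
        return int(self.counts[i, j])


@dataclass
class CoreSet:
    """Core pairs/groups plus flagged core single ingredients.

    ``core_singles`` come from a parameterized row-mass rule (nodes in no
    core pair whose total co-occurrence mass is in the top fraction); this
    rule is a labelled heuristic, not part of the counting scheme, and the
    fraction used is recorded in ``rule``.
    """

    core_pairs: List[Tuple[str, str]]
    core_groups: List[List[str]]
    core_singles: List[str]
    rule: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "core_pairs": [list(p) for p in self.core_pairs],
                "core_groups": self.core_groups,
                "core_singles": self.core_singles,
                "single_rule": dict(
                    self.rule, note="row-mass heuristic, non-canonical"
                ),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CoreSet":
        obj = json.loads(text)
        return cls(
            core_pairs=[tuple(p) for p in obj["core_pairs"]],
            core_groups=obj["core_groups"],
            core_singles=obj["core_singles"],
            rule=obj.get("single_rule", {}),
        )


def cooccurrence_matrix(
    partitions: Sequence[Partition], universe: Sequence[str]
) -> CooccurrenceMatrix:
    """Tally shared-community counts over one partition per threshold."""
    if not partitions:
        raise ValidationError("need at least one partition")
    universe = list(universe)
    uset = set(universe)
    for p in partitions:
        if set(p.assignment) != uset:
            raise ValidationError(
                "all partitions must cover the same node universe"
            )
    n = len(universe)
    counts = np.zeros((n, n), dtype=int)
    for p in partitions:
        labels = p.labels(universe)
        same = labels[:, None] == labels[None, :]
        counts += same.astype(int)
    return CooccurrenceMatrix(
        order=universe, counts=counts, n_thresholds=len(partitions)
    )


def bandwidth(pattern: np.ndarray) -> int:
    """Max |i - j| over nonzero off-diagonal entries (0 if none)."""
    ii, jj = np.nonzero(pattern)
    off = ii != jj
    if not off.any():
        return 0
    return int(np.abs(ii[off] - jj[off]).max())


def rcm_order(matrix: CooccurrenceMatrix, reverse: bool = True) -> np.ndarray:
    """Cuthill-McKee permutation of the binarized (counts > 0) pattern.

    Reverse ordering (the bandwidth-reduction standard) by default; pass
    ``reverse=False`` for the forward ordering.  Cuthill-McKee is a
    heuristic, so if the computed ordering would widen the band relative to
    the input order the identity permutation is returned instead: the
    contract is that reordering never increases bandwidth.
    """
    pattern = (matrix.counts > 0).astype(np.int8)
    np.fill_diagonal(pattern, 0)
    perm = np.asarray(
        reverse_cuthill_mckee(csr_matrix(pattern), symmetric_mode=True)
    )
    if not reverse:
        perm = perm[::-1].copy()
    if bandwidth(pattern[np.ix_(perm, perm)]) > bandwidth(pattern):
        perm = np.arange(len(matrix.order))
    return perm


def render_heatmap(
    matrix: CooccurrenceMatrix, perm: np.ndarray, path
) -> None:
    """Write a grayscale heat map PNG plus the permuted matrix as TSV.

    Saturation is linear in the count: 0 -> white, T -> black.
    """
    if sorted(perm.tolist()) != list(range(len(matrix.order))):
        raise ValidationError("perm is not a permutation of the node order")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    permuted = matrix.counts[np.ix_(perm, perm)]
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(
        permuted,
        cmap="Greys",
        vmin=0,
        vmax=matrix.n_thresholds,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="thresholds sharing a community")
    ax.set_xlabel("ingredient (Cuthill-McKee order)")
    ax.set_ylabel("ingredient (Cuthill-McKee order)")
    fig.savefig(path, dpi=150)
    plt.close(fig)

    tsv_path = str(path) + ".tsv"
    names = [matrix.order[i] for i in perm]
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for name, row in zip(names, permuted):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def extract_core(
    matrix: CooccurrenceMatrix, single_top_fraction: float = 0.05
) -> CoreSet:
    """Extract core pairs, their connected groups, and core singles.

    Core pairs are off-diagonal entries equal to T.  Core singles are nodes
    belonging to no core pair whose row mass (off-diagonal sum) falls in the
    top ``single_top_fraction`` of all row masses.
    """
    if matrix.n_thresholds < 1:
        raise ValidationError("need at least one threshold")
    if not 0.0 < single_top_fraction <= 1.0:
        raise ValidationError("single_top_fraction must be in (0, 1]")
    n = len(matrix.order)
    T = matrix.n_thresholds
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.counts[i, j] == T:
                pairs.append((matrix.order[i], matrix.order[j]))

    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(pairs)
    groups = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda grp: grp[0],
    )
    in_pair = set(g.nodes)

    row_mass = matrix.counts.sum(axis=1) - np.diag(matrix.counts)
    n_top = max(1, int(np.ceil(single_top_fraction * n)))
    cutoff = np.sort(row_mass)[::-1][n_top - 1]
    singles = sorted(
        matrix.order[i]
        for i in range(n)
        if matrix.order[i] not in in_pair
        and row_mass[i] >= cutoff
        and row_mass[i] > 0
    )
    return CoreSet(
        core_pairs=pairs,
        core_groups=groups,
        core_singles=singles,
        rule={"single_top_fraction": single_top_fraction},
    )


def write_matrix(matrix: CooccurrenceMatrix, path) -> None:
    """Matrix TSV with a header row/column of ingredient tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.order) + "\n")
        for name, row in zip(matrix.order, matrix.counts):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
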