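"""Maximal dependence decomposition (MDD) of site fragments into motif subgroups.

MDD recursively partitions a set of aligned fragments by the pair of
flanking window positions whose residue-group occupancies are most strongly
dependent.  Residues are first mapped into five physicochemical groups
(polar, acidic, basic, hydrophobic, aromatic); for every ordered pair of
flanking positions (i, j) a 5 x 5 contingency table of group co-occurrence
is built and scored with the chi-square statistic

    chi2(Ai, Aj) = sum_mn (X_mn - E_mn)^2 / E_mn,   E_mn = X_mR * X_Cn / X.

A position's dependence score is Score(Ai) = sum_{j != i} chi2(Ai, Aj).  If
any pair exceeds the strong-dependence threshold (default 34.3), the set is
split at the argmax-Score position into fragments carrying the dominant
residue group there versus fragments lacking it, and the two halves are
decomposed recursively.  Subgroups at or below ``max_cluster_size`` are
left intact, so the recursion always terminates.  Leaves are named GSH1,
GSH2, ... in descending size order; the final leaf may carry no conserved
motif at all.

The centre position 0 always holds the candidate cysteine and is never a
split candidate.  Fragments with 'X' at a queried position are excluded
from that contingency table; at split time they follow the "lacks group"
branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .features import PWM, build_pwm
from .seq_data import AA_ORDER, SiteFragment, window_offsets

GROUP_ORDER = ("polar", "acidic", "basic", "hydrophobic", "aromatic")

#: Default five-group partition of the 20 standard residues.  Basic residues
#: are H/K/R (the positively charged side chains whose enrichment flanking
#: glutathionylated cysteines drives most observed motifs); 'X' belongs to
#: no group.
DEFAULT_GROUPING: dict[str, str] = {
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "HKR"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "hydrophobic" for aa in "AILMPV"},
    **{aa: "polar" for aa in "CGNQST"},
}

#: Strong-dependence chi-square cutoff for a 5 x 5 table.
DEFAULT_THRESHOLD = 34.3

#: Subgroups at or below this size are never divided further.
DEFAULT_MAX_CLUSTER_SIZE = 300


@dataclass(frozen=True)
class AAGrouping:
    """A disjoint partition of the 20 standard residues into the five groups."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(AA_ORDER) - set(self.mapping)
        if missing:
            raise ValueError(f"residues without a group: {sorted(missing)}")
        bad = {aa: g for aa, g in self.mapping.items() if g not in GROUP_ORDER}
        if bad:
            raise ValueError(f"unknown groups: {bad}")

    def group_index(self, residue: str) -> int:
        """0-4 for a standard residue, -1 for 'X'."""
        if residue == "X":
            return -1
        return GROUP_ORDER.index(self.mapping[residue])

    def members(self, group: str) -> str:
        return "".join(aa for aa in AA_ORDER if self.mapping[aa] == group)

    @classmethod
    def default(cls) -> "AAGrouping":
        return cls(dict(DEFAULT_GROUPING))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAGrouping":
        """Read a grouping file: residue<TAB>group, one row per residue."""
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            aa, group = line.split("\t")
            mapping[aa.strip().upper()] = group.strip().lower()
        return cls(mapping)


@dataclass(frozen=True)
class ContingencyTable:
    """5 x 5 group co-occurrence counts between two window positions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (5, 5) or (c < 0).any():
            raise ValueError("contingency table must be 5x5 non-negative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def degrees_of_freedom(self) -> int:
        return (self.counts.shape[0] - 1) * (self.counts.shape[1] - 1)


@dataclass
class MDDNode:
    """A node of the decomposition tree.

    ``path`` records the (position, group, has|lacks) predicates satisfied
    by every fragment in the node, from the root down.  Leaves carry a
    ``name`` (GSH1..GSHk) assigned after the full tree is built.
    """

    fragments: list[SiteFragment]
    path: list[tuple[int, str, str]] = field(default_factory=list)
    split: Optional[tuple[int, str]] = None
    children: Optional[tuple["MDDNode", "MDDNode"]] = None
    name: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def size(self) -> int:
        return len(self.fragments)

    def describe_path(self) -> str:
        if not self.path:
            return "(no motif constraint)"
        return "; ".join(
            f"{'has' if rel == 'has' else 'lacks'} {group} at {pos:+d}"
            for pos, group, rel in self.path
        )


@dataclass
class MDDTree:
    """The full decomposition: root node, ordered leaves, and the parameters used."""

    root: MDDNode
    threshold: float
    max_cluster_size: int
    grouping: AAGrouping

    @property
    def leaves(self) -> list[MDDNode]:
        out: list[MDDNode] = []

        def walk(node: MDDNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return sorted(out, key=lambda leaf: -leaf.size)

    def route(self, fragment: SiteFragment) -> MDDNode:
        """Follow the split predicates from the root to the leaf a fragment satisfies."""
        node = self.root
        while not node.is_leaf:
            pos, group = node.split
            idx = self.grouping.group_index(fragment.residue_at(pos))
            has = idx == GROUP_ORDER.index(group)
            node = node.children[0] if has else node.children[1]
        return node

    def to_dict(self) -> dict:
        def node_dict(node: MDDNode) -> dict:
            d: dict = {"size": node.size, "path": [list(p) for p in node.path]}
            if node.is_leaf:
                d["name"] = node.name
            else:
                pos, group = node.split
                d["split"] = {"position": pos, "group": group}
                d["has"] = node_dict(node.children[0])
                d["lacks"] = node_dict(node.children[1])
            return d

        return {
            "threshold": self.threshold,
            "max_cluster_size": self.max_cluster_size,
            "grouping": {aa: self.grouping.mapping[aa] for aa in AA_ORDER},
            "n_fragments": self.root.size,
            "n_leaves": len(self.leaves),
            "tree": node_dict(self.root),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def render(self) -> str:
        """Indented text rendering of the tree."""
        lines: list[str] = []

        def walk(node: MDDNode, depth: int, tag: str) -> None:
            indent = "  " * depth
            if node.is_leaf:
                lines.append(f"{indent}{tag}{node.name} (n={node.size}): {node.describe_path()}")
            else:
                pos, group = node.split
                lines.append(f"{indent}{tag}split on {group} at {pos:+d} (n={node.size})")
                walk(node.children[0], depth + 1, "has:   ")
                walk(node.children[1], depth + 1, "lacks: ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _group_matrix(
    fragments: Sequence[SiteFragment], grouping: AAGrouping
) -> tuple[np.ndarray, list[int]]:
    """(n_fragments x n_offsets) matrix of group indices (-1 for 'X') and the offsets."""
    n = fragments[0].n
    offsets = window_offsets(n)
    mat = np.empty((len(fragments), len(offsets)), dtype=np.int8)
    for fi, frag in enumerate(fragments):
        for oi, off in enumerate(offsets):
            mat[fi, oi] = grouping.group_index(frag.residue_at(off))
    return mat, offsets


def contingency(
    fragments: Sequence[SiteFragment],
    i: int,
    j: int,
    grouping: AAGrouping | None = None,
) -> ContingencyTable:
    """Group co-occurrence table between window positions ``i`` and ``j``.

    Fragments with 'X' at either position are excluded.
    """
    if i == j:
        raise ValueError("positions must differ")
    grouping = grouping or AAGrouping.default()
    counts = np.zeros((5, 5))
    for frag in fragments:
        gi = grouping.group_index(frag.residue_at(i))
        gj = grouping.group_index(frag.residue_at(j))
        if gi < 0 or gj < 0:
            continue
        counts[gi, gj] += 1
    return ContingencyTable(counts)


def chi_square(table: ContingencyTable) -> float:
    """Chi-square dependence statistic; cells with zero expected count contribute 0."""
    X = table.total
    if X == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(table.row_sums, table.col_sums) / X
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            expected > 0, (table.counts - expected) ** 2 / expected, 0.0
        )
    return float(terms.sum())


def _chi_square_from_counts(counts: np.ndarray) -> float:
    return chi_square(ContingencyTable(counts))


def _pair_chi_squares(mat: np.ndarray) -> np.ndarray:
    """Symmetric matrix of chi-square values over all offset pairs.

    ``mat`` is the fragment-by-offset group-index matrix; entries with -1
    ('X') are dropped pairwise.  Vectorised over the 5x5 cells via bincount.
    """
    n_off = mat.shape[1]
    out = np.zeros((n_off, n_off))
    for a in range(n_off):
        ga = mat[:, a]
        for b in range(a + 1, n_off):
            gb = mat[:, b]
            keep = (ga >= 0) & (gb >= 0)
            if not keep.any():
                continue
            flat = ga[keep].astype(np.int64) * 5 + gb[keep]
            counts = np.bincount(flat, minlength=25).reshape(5, 5).astype(float)
            total = counts.sum()
            expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
            out[a, b] = out[b, a] = terms.sum()
    return out


def position_score(
    fragments: Sequence[SiteFragment],
    i: int,
    grouping: AAGrouping | None = None,
) -> float:
    """Score(Ai): summed chi-square dependence of position ``i`` with every other position."""
    grouping = grouping or AAGrouping.default()
    total = 0.0
    for j in window_offsets(fragments[0].n):
        if j == i:
            continue
        table = contingency(fragments, i, j, grouping)
        if table.total > 0:
            total += chi_square(table)
    return total


def _choose_group(mat: np.ndarray, pos_idx: int, chi: np.ndarray) -> str:
    """Dominant residue group at a split position.

    For each candidate group the position's occupancy is binarized into
    has-group / lacks-group, and the summed 2 x 5 chi-square of that binary
    indicator against every partner position is computed; the group whose
    presence/absence explains the most dependence wins.  Ties resolve in
    fixed :data:`GROUP_ORDER`.
    """
    split_strength = np.zeros(5)
    ga = mat[:, pos_idx]
    for b in range(mat.shape[1]):
        if b == pos_idx or chi[pos_idx, b] == 0:
            continue
        gb = mat[:, b]
        keep = (ga >= 0) & (gb >= 0)
        flat = ga[keep].astype(np.int64) * 5 + gb[keep]
        counts = np.bincount(flat, minlength=25).reshape(5, 5).astype(float)
        total = counts.sum()
        if total == 0:
            continue
        col_sums = counts.sum(axis=0)
        for g in range(5):
            binary = np.vstack([counts[g], col_sums - counts[g]])
            expected = np.outer(binary.sum(axis=1), col_sums) / total
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(
                    expected > 0, (binary - expected) ** 2 / expected, 0.0
                )
            split_strength[g] += terms.sum()
    return GROUP_ORDER[int(np.argmax(split_strength))]


def best_split(
    fragments: Sequence[SiteFragment],
    grouping: AAGrouping | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> Optional[tuple[int, str]]:
    """The (position, group) to split on, or None when no pair is strongly dependent.

    A split exists iff some position pair's chi-square exceeds ``threshold``.
    The split position is the argmax of Score(Ai); ties resolve to the
    smallest ``|i|``, negative before positive.  The group is the dominant
    one at that position (see :func:`_choose_group`).
    """
    grouping = grouping or AAGrouping.default()
    if not fragments:
        return None
    mat, offsets = _group_matrix(fragments, grouping)
    chi = _pair_chi_squares(mat)
    if chi.max() <= threshold:
        return None
    scores = chi.sum(axis=1)
    order = sorted(
        range(len(offsets)),
        key=lambda idx: (-scores[idx], abs(offsets[idx]), offsets[idx]),
    )
    pos_idx = order[0]
    group = _choose_group(mat, pos_idx, chi)
    return offsets[pos_idx], group


def mdd_cluster(
    fragments: Sequence[SiteFragment],
    grouping: AAGrouping | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    max_cluster_size: int = DEFAULT_MAX_CLUSTER_SIZE,
) -> MDDTree:
    """Recursively decompose fragments into motif subgroups.

    A node is divided only while its size exceeds ``max_cluster_size`` and a
    strong dependence remains; a proposed split that would leave one side
    empty is discarded (the node becomes a leaf).  Leaves partition the
    input and are named GSH1..GSHk in descending size order.
    """
    if not fragments:
        raise ValueError("cannot cluster an empty fragment set")
    if max_cluster_size < 1:
        raise ValueError("max_cluster_size must be >= 1")
    grouping = grouping or AAGrouping.default()

    def build(node: MDDNode) -> None:
        if node.size <= max_cluster_size:
            return
        split = best_split(node.fragments, grouping, threshold)
        if split is None:
            return
        pos, group = split
        gidx = GROUP_ORDER.index(group)
        has = [f for f in node.fragments
               if grouping.group_index(f.residue_at(pos)) == gidx]
        lacks = [f for f in node.fragments
                 if grouping.group_index(f.residue_at(pos)) != gidx]
        if not has or not lacks:
            return
        node.split = split
        node.children = (
            MDDNode(has, node.path + [(pos, group, "has")]),
            MDDNode(lacks, node.path + [(pos, group, "lacks")]),
        )
        build(node.children[0])
        build(node.children[1])

    root = MDDNode(list(fragments))
    build(root)
    tree = MDDTree(root, threshold=threshold,
                   max_cluster_size=max_cluster_size, grouping=grouping)
    for rank, leaf in enumerate(tree.leaves, start=1):
        leaf.name = f"GSH{rank}"
    return tree


def leaf_logo(node: MDDNode) -> PWM:
    """Position weight matrix over a leaf's member fragments (its text sequence logo)."""
    if not node.is_leaf:
        raise ValueError("leaf_logo requires a leaf node")
    return build_pwm(node.fragments)
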