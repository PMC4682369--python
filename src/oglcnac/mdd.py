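"""Maximal dependence decomposition of positive peptide windows.

The 20 amino acids are collapsed to five physicochemical groups (polar,
acidic, basic, hydrophobic, aromatic). For every pair of non-center
window positions a 5x5 contingency table of group co-occurrence is built
and tested with the chi-squared statistic

    chi2(Ai, Aj) = sum_mn (X_mn - E_mn)^2 / E_mn,   E_mn = X_mR * X_Cn / X.

A subgroup whose strongest pairwise statistic exceeds the critical value
(34.3 = upper 0.005 quantile of chi-squared with 16 df) is split on the
position with the largest aggregate dependence D_i = sum_j chi2(i, j),
into windows that carry the modal group at that position and the rest.
Recursion stops at the critical value or a minimum subgroup size, giving
a binary tree whose leaves are the substrate-motif subgroups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .alphabet import AMINO_ACIDS
from .seq_windows import PeptideWindow

GROUPS: tuple[str, ...] = ("polar", "acidic", "basic", "hydrophobic", "aromatic")

#: Partition of the 20 letters into the five groups. Configurable: pass an
#: alternative mapping to any function taking a ``scheme`` argument.
DEFAULT_GROUP_SCHEME: dict[str, str] = {
    **{a: "polar" for a in "STCNQY"},
    **{a: "acidic" for a in "DE"},
    **{a: "basic" for a in "HKR"},
    **{a: "hydrophobic" for a in "AGILMPV"},
    **{a: "aromatic" for a in "FW"},
}

#: Group symbol for 'X' and '-': excluded from all counts.
NULL_GROUP = None

#: Upper 0.005 critical value of chi-squared with 16 df, rounded to 1 dp.
CHI2_CUTOFF = 34.3
DEFAULT_MIN_SIZE = 30


def chi2_critical(p: float = 0.005, df: int = 16) -> float:
    """Upper critical value of the chi-squared distribution."""
    return float(chi2_dist.ppf(1.0 - p, df))


def validate_scheme(scheme: dict[str, str]) -> None:
    """Check that the scheme maps each of the 20 letters to one of the five
    groups and that no group is empty."""
    letters = set(scheme)
    if letters != set(AMINO_ACIDS):
        raise ValueError("scheme must map exactly the 20 amino-acid letters")
    used = set(scheme.values())
    if not used <= set(GROUPS):
        raise ValueError(f"unknown group labels: {sorted(used - set(GROUPS))}")
    if used != set(GROUPS):
        raise ValueError(f"empty groups: {sorted(set(GROUPS) - used)}")


def read_scheme(path) -> dict[str, str]:
    """Read a letter→group table (two whitespace-separated columns)."""
    scheme = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            letter, group = line.split()
            scheme[letter.upper()] = group.lower()
    validate_scheme(scheme)
    return scheme


def group_encode(fragment: str, scheme: dict[str, str] | None = None) -> list:
    """Map each character to its group label; 'X' and '-' map to None."""
    scheme = DEFAULT_GROUP_SCHEME if scheme is None else scheme
    return [scheme.get(c, NULL_GROUP) for c in fragment]


@dataclass
class ContingencyTable:
    """5x5 group co-occurrence counts between two window positions."""

    counts: np.ndarray  # shape (5, 5), rows = group at i, cols = group at j
    position_i: int
    position_j: int

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DependenceResult:
    position_i: int
    position_j: int
    chi2: float


def _offset_to_index(offset: int, w: int) -> int:
    if offset == 0:
        raise ValueError("the center position (offset 0) is fixed S/T and "
                         "excluded from dependence testing")
    if not -w <= offset <= w:
        raise ValueError(f"offset {offset} outside window [-{w}, {w}]")
    return offset + w


def noncenter_offsets(w: int) -> list[int]:
    return [o for o in range(-w, w + 1) if o != 0]


def contingency(
    fragments: Sequence[PeptideWindow],
    i: int,
    j: int,
    scheme: dict[str, str] | None = None,
) -> ContingencyTable:
    """Count group co-occurrence between offsets ``i`` and ``j``.

    Fragments with a null symbol ('X' or '-') at either position are
    skipped, so the table total may be less than the fragment count.
    """
    if i == j:
        raise ValueError("positions must differ")
    scheme = DEFAULT_GROUP_SCHEME if scheme is None else scheme
    w = fragments[0].halfwidth
    gi = GROUPS.index  # group label -> row/col
    ii, jj = _offset_to_index(i, w), _offset_to_index(j, w)
    counts = np.zeros((5, 5), dtype=np.int64)
    for frag in fragments:
        a = scheme.get(frag.fragment[ii], NULL_GROUP)
        b = scheme.get(frag.fragment[jj], NULL_GROUP)
        if a is None or b is None:
            continue
        counts[gi(a), gi(b)] += 1
    return ContingencyTable(counts=counts, position_i=i, position_j=j)


def chi_square(table: ContingencyTable) -> float:
    """Chi-squared statistic of the 5x5 table; cells with zero expected
    count contribute nothing."""
    X = table.counts.astype(float)
    total = X.sum()
    if total < 1:
        raise ValueError("contingency table is empty")
    expected = np.outer(table.row_marginals, table.col_marginals) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (X - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def dependence_scan(
    fragments: Sequence[PeptideWindow],
    scheme: dict[str, str] | None = None,
    w: int | None = None,
) -> list[DependenceResult]:
    """chi-squared for every unordered pair of non-center positions."""
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    if w is None:
        w = fragments[0].halfwidth
    out = []
    for i, j in combinations(noncenter_offsets(w), 2):
        stat = chi_square(contingency(fragments, i, j, scheme))
        out.append(DependenceResult(position_i=i, position_j=j, chi2=stat))
    return out


def modal_group(
    fragments: Sequence[PeptideWindow],
    offset: int,
    scheme: dict[str, str] | None = None,
) -> Optional[str]:
    """Most frequent group at ``offset`` (ties broken in GROUPS order);
    None when every fragment has a null symbol there."""
    scheme = DEFAULT_GROUP_SCHEME if scheme is None else scheme
    w = fragments[0].halfwidth
    idx = _offset_to_index(offset, w)
    counts = dict.fromkeys(GROUPS, 0)
    for frag in fragments:
        g = scheme.get(frag.fragment[idx], NULL_GROUP)
        if g is not None:
            counts[g] += 1
    best = max(GROUPS, key=lambda g: (counts[g], -GROUPS.index(g)))
    return best if counts[best] > 0 else None


def choose_split(
    fragments: Sequence[PeptideWindow],
    scheme: dict[str, str] | None = None,
    w: int | None = None,
    chi2_cutoff: float = CHI2_CUTOFF,
) -> Optional[tuple[int, str, float]]:
    """Pick the split (position, group, max pairwise chi2), or None.

    The split position maximizes the aggregate D_i = sum_j chi2(i, j)
    (tie → smaller offset); its modal group is the split group. Returns
    None when no pairwise statistic exceeds the cutoff.
    """
    results = dependence_scan(fragments, scheme, w)
    max_pair = max(r.chi2 for r in results)
    if max_pair <= chi2_cutoff:
        return None
    agg: dict[int, float] = {}
    for r in results:
        agg[r.position_i] = agg.get(r.position_i, 0.0) + r.chi2
        agg[r.position_j] = agg.get(r.position_j, 0.0) + r.chi2
    best = max(sorted(agg), key=lambda o: agg[o])
    group = modal_group(fragments, best, scheme)
    if group is None:
        return None
    return best, group, max_pair


@dataclass
class MDDNode:
    """A node of the MDD tree; leaves carry the motif subgroup members."""

    members: list = field(repr=False)
    split_position: Optional[int] = None
    split_group: Optional[str] = None
    child_with: Optional["MDDNode"] = None
    child_without: Optional["MDDNode"] = None
    leaf_id: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.child_with is None and self.child_without is None

    def leaves(self) -> list["MDDNode"]:
        """Leaves in depth-first, with-branch-first order."""
        if self.is_leaf:
            return [self]
        return self.child_with.leaves() + self.child_without.leaves()

    @property
    def size(self) -> int:
        return len(self.members)


def mdd_cluster(
    fragments: Sequence[PeptideWindow],
    scheme: dict[str, str] | None = None,
    w: int | None = None,
    chi2_cutoff: float = CHI2_CUTOFF,
    min_size: int = DEFAULT_MIN_SIZE,
    leaf_prefix: str = "OGT",
) -> MDDNode:
    """Recursively partition positive fragments into motif subgroups.

    A node becomes a leaf when it has fewer than ``min_size`` members,
    when no position pair exceeds ``chi2_cutoff``, or when the proposed
    split would be degenerate (an empty child, or a (position, group)
    already used on the path). Leaves are labeled ``OGT1..OGTk`` in
    depth-first, with-branch-first order.
    """
    if not fragments:
        raise ValueError("fragments must be non-empty")
    scheme = DEFAULT_GROUP_SCHEME if scheme is None else scheme
    validate_scheme(scheme)
    if w is None:
        w = fragments[0].halfwidth

    def build(members: list, used: frozenset) -> MDDNode:
        node = MDDNode(members=members)
        if len(members) < min_size or len(members) < 2:
            return node
        chosen = choose_split(members, scheme, w, chi2_cutoff)
        if chosen is None:
            return node
        pos, group, _ = chosen
        if (pos, group) in used:
            return node
        idx = _offset_to_index(pos, w)
        with_g = [m for m in members if scheme.get(m.fragment[idx]) == group]
        without_g = [m for m in members if scheme.get(m.fragment[idx]) != group]
        if not with_g or not without_g:
            return node
        node.split_position = pos
        node.split_group = group
        node.child_with = build(with_g, used | {(pos, group)})
        node.child_without = build(without_g, used)
        return node

    root = build(list(fragments), frozenset())
    for k, leaf in enumerate(root.leaves(), start=1):
        leaf.leaf_id = f"{leaf_prefix}{k}"
    return root


# ---------------------------------------------------------------------------
# Serialization

def tree_to_dict(node: MDDNode, include_members: bool = True) -> dict:
    d: dict = {"size": node.size}
    if node.is_leaf:
        d["leaf_id"] = node.leaf_id
        if include_members:
            d["members"] = [m.fragment for m in node.members]
    else:
        d["split_position"] = node.split_position
        d["split_group"] = node.split_group
        d["with"] = tree_to_dict(node.child_with, include_members)
        d["without"] = tree_to_dict(node.child_without, include_members)
    return d


def write_tree(node: MDDNode, path, include_members: bool = True) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(node, include_members), fh, indent=1, sort_keys=True)
        fh.write("\n")
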