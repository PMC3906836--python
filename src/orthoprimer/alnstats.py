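"""Alignment variability statistics and small-parsimony machinery.

Per-column classification (constant / variable-uninformative /
parsimony-informative), minimum-change lower bounds, the Fitch
small-parsimony score of an alignment on a tree, the consistency index,
and quality-masked polymorphism counts for strain panels.

Gaps — and bases failing a quality mask — are treated as missing data
throughout: a missing cell contributes no state and no constraint.  A
parsimony-informative column has at least two states each observed in
at least two rows; the minimum possible number of changes at a column
is (number of distinct observed states) - 1, a tree-free lower bound on
what any topology must spend there.  The consistency index CI is the
ratio of that bound to the realised tree length, computed over columns
whose bound is positive; CI = 1 means the tree explains the data with
no homoplasy.

Trees are handled as nested tuples of leaf labels (any binary rooting
of the unrooted topology); Newick input is parsed through dendropy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence, Union

import dendropy

from .errors import AlignmentError, FormatError, SizeError
from .seqio import Alignment, QualityMask

Tree = Union[str, tuple]

_MISSING = {"dna": {"-", "N"}, "protein": {"-", "X"}}


# ---------------------------------------------------------------------------
# tree plumbing


def parse_newick(text: str) -> Tree:
    """Newick string -> nested-tuple tree (binary; root trifurcation ok)."""
    dt = dendropy.Tree.get(data=text, schema="newick")

    def conv(node) -> Tree:
        kids = node.child_nodes()
        if not kids:
            if node.taxon is None or node.taxon.label is None:
                raise FormatError("unlabelled leaf in Newick tree")
            return node.taxon.label
        subs = [conv(k) for k in kids]
        if len(subs) == 1:
            return subs[0]
        if len(subs) == 2:
            return (subs[0], subs[1])
        if len(subs) == 3:  # unrooted convention: fold into a binary rooting
            return ((subs[0], subs[1]), subs[2])
        raise FormatError("tree must be binary (multifurcation found)")

    return conv(dt.seed_node)


def to_newick(tree: Tree) -> str:
    def fmt(node: Tree) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(fmt(c) for c in node) + ")"

    return fmt(tree) + ";"


def tree_leaves(tree: Tree) -> set[str]:
    if isinstance(tree, str):
        return {tree}
    out: set[str] = set()
    for c in tree:
        out |= tree_leaves(c)
    return out


def tree_splits(tree: Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology.

    Each split is represented by the leaf set on one side, with the
    side chosen canonically, so two trees are topologically identical
    iff their split sets are equal.
    """
    all_leaves = frozenset(tree_leaves(tree))
    splits: set[frozenset[str]] = set()

    def walk(node: Tree) -> frozenset[str]:
        if isinstance(node, str):
            return frozenset({node})
        below = frozenset()
        for c in node:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return below

    walk(tree)
    return frozenset(splits)


def same_topology(a: Tree, b: Tree) -> bool:
    if tree_leaves(a) != tree_leaves(b):
        return False
    return tree_splits(a) == tree_splits(b)


# ---------------------------------------------------------------------------
# per-column state extraction


def _observed_states(
    aln: Alignment, j: int, mask: QualityMask | None
) -> list[str | None]:
    """Per-row state at column j; None for gap/masked/ambiguous cells."""
    missing = _MISSING[aln.kind]
    out: list[str | None] = []
    for i, row in enumerate(aln.rows):
        c = row[j]
        if c in missing or (mask is not None and not mask.trusted[i][j]):
            out.append(None)
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# site classification and minimum changes


@dataclass(frozen=True)
class SiteClass:
    category: str  # constant | variable_uninformative | parsimony_informative
    states: tuple[tuple[str, int], ...]  # observed non-missing state counts


def classify_sites(
    aln: Alignment, mask: QualityMask | None = None
) -> list[SiteClass]:
    """Classify every column of the alignment.

    Columns with fewer than two non-missing cells are constant by
    convention; parsimony-informative requires >= 2 distinct states
    each in >= 2 rows.
    """
    if aln.nrows < 2:
        raise AlignmentError("need at least 2 rows")
    if mask is not None and not mask.matches(aln):
        raise AlignmentError("quality mask does not match the alignment")
    out = []
    for j in range(aln.length):
        counts = Counter(s for s in _observed_states(aln, j, mask) if s is not None)
        n_obs = sum(counts.values())
        if n_obs < 2 or len(counts) == 1:
            cat = "constant"
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            cat = "parsimony_informative"
        else:
            cat = "variable_uninformative"
        out.append(SiteClass(cat, tuple(sorted(counts.items()))))
    return out


def count_classes(sites: Iterable[SiteClass]) -> dict[str, int]:
    c = Counter(s.category for s in sites)
    return {
        "constant": c.get("constant", 0),
        "variable_uninformative": c.get("variable_uninformative", 0),
        "parsimony_informative": c.get("parsimony_informative", 0),
    }


def min_changes(
    aln: Alignment, mask: QualityMask | None = None
) -> tuple[list[int], int]:
    """Per-column lower bound on substitutions and the total.

    Each column needs at least (distinct observed states - 1) changes
    on any tree; missing cells are excluded.
    """
    if aln.nrows < 2:
        raise AlignmentError("need at least 2 rows")
    per_col = []
    for j in range(aln.length):
        states = {s for s in _observed_states(aln, j, mask) if s is not None}
        per_col.append(max(len(states) - 1, 0))
    return per_col, sum(per_col)


# ---------------------------------------------------------------------------
# Fitch small parsimony


def _fitch_site(node: Tree, leaf_state: dict[str, str | None]) -> tuple[frozenset | None, int]:
    """Postorder Fitch pass; None plays the role of the universal set."""
    if isinstance(node, str):
        s = leaf_state[node]
        return (None if s is None else frozenset({s})), 0
    (ls, lc), (rs, rc) = (_fitch_site(c, leaf_state) for c in node)
    changes = lc + rc
    if ls is None:
        return rs, changes
    if rs is None:
        return ls, changes
    inter = ls & rs
    if inter:
        return inter, changes
    return ls | rs, changes + 1


@dataclass
class ParsimonyResult:
    tree: Tree
    total_changes: int
    per_site_changes: list[int]
    min_possible: int
    ci: float


def fitch_score(
    tree: Tree | str,
    aln: Alignment,
    mask: QualityMask | None = None,
) -> ParsimonyResult:
    """Fitch parsimony score of an alignment on a tree, with CI.

    Unordered states, unit cost; missing data contributes no
    constraint.  The score is invariant to the rooting of the unrooted
    topology.  CI excludes columns whose minimum-change bound is zero
    from both numerator and denominator; it is 1.0 when no column
    requires extra changes (including the degenerate no-variation
    case).
    """
    if isinstance(tree, str) and (";" in tree or "(" in tree):
        tree = parse_newick(tree)
    leaves = tree_leaves(tree)
    if leaves != set(aln.names):
        raise AlignmentError(
            f"tree leaves {sorted(leaves)} do not match alignment rows "
            f"{sorted(aln.names)}"
        )
    if mask is not None and not mask.matches(aln):
        raise AlignmentError("quality mask does not match the alignment")
    per_site = []
    for j in range(aln.length):
        states = _observed_states(aln, j, mask)
        leaf_state = dict(zip(aln.names, states))
        _, changes = _fitch_site(tree, leaf_state)
        per_site.append(changes)
    per_min, _ = min_changes(aln, mask)
    num = sum(m for m in per_min if m > 0)
    den = sum(c for m, c in zip(per_min, per_site) if m > 0)
    ci = 1.0 if den == 0 else num / den
    return ParsimonyResult(
        tree=tree,
        total_changes=sum(per_site),
        per_site_changes=per_site,
        min_possible=sum(per_min),
        ci=ci,
    )


# ---------------------------------------------------------------------------
# exhaustive search over unrooted topologies


def _insertions(sub: Tree, x: str) -> Iterator[Tree]:
    """All ways of attaching leaf x onto an edge of a rooted subtree."""
    yield (sub, x)  # insert on the edge above this subtree
    if not isinstance(sub, str):
        left, right = sub
        for t in _insertions(left, x):
            yield (t, right)
        for t in _insertions(right, x):
            yield (left, t)


def enumerate_topologies(names: Sequence[str]) -> Iterator[Tree]:
    """All (2n-5)!! unrooted binary topologies, rooted at the first leaf."""
    names = list(names)
    if len(names) < 3:
        raise SizeError("need at least 3 taxa")
    first, rest = names[0], names[1:]

    def build(sub: Tree, todo: list[str]) -> Iterator[Tree]:
        if not todo:
            yield (first, sub)
            return
        x, remaining = todo[0], todo[1:]
        for t in _insertions(sub, x):
            yield from build(t, remaining)

    yield from build((rest[0], rest[1]), rest[2:])


def exhaustive_parsimony(
    aln: Alignment,
    mask: QualityMask | None = None,
    max_taxa: int = 9,
) -> tuple[list[Tree], int]:
    """Score every unrooted topology; return all ties for the minimum.

    Desk-scale exact search: the number of topologies is (2n-5)!!, so
    the taxon count is capped (default 9, i.e. 135135 trees).  Only
    parsimony-informative column patterns are re-scored per topology —
    a column in which at most one state occurs more than once costs its
    minimum-change bound on *every* binary tree, so those columns
    contribute a constant offset.  The returned score equals the full
    Fitch length of the best tree(s).
    """
    if aln.nrows > max_taxa:
        raise SizeError(f"{aln.nrows} taxa exceeds exhaustive cap {max_taxa}")
    classes = classify_sites(aln, mask)
    per_min, _ = min_changes(aln, mask)
    offset = sum(
        m for m, c in zip(per_min, classes) if c.category != "parsimony_informative"
    )
    patterns = Counter(
        tuple(_observed_states(aln, j, mask))
        for j, c in enumerate(classes)
        if c.category == "parsimony_informative"
    )
    best_score: int | None = None
    best: list[Tree] = []
    for tree in enumerate_topologies(aln.names):
        score = offset
        for pattern, count in patterns.items():
            leaf_state = dict(zip(aln.names, pattern))
            _, changes = _fitch_site(tree, leaf_state)
            score += count * changes
        if best_score is None or score < best_score:
            best_score = score
            best = [tree]
        elif score == best_score:
            best.append(tree)
    assert best_score is not None
    return best, best_score


# ---------------------------------------------------------------------------
# strain panels


def strain_polymorphism(
    aln: Alignment, mask: QualityMask | None = None
) -> tuple[int, int]:
    """(n_sites, n_variable) for a strain panel under a quality mask.

    A site is variable when at least two distinct trusted, non-gap
    states are observed.
    """
    if aln.nrows < 2:
        raise AlignmentError("need at least 2 rows")
    n_variable = 0
    for j in range(aln.length):
        states = {s for s in _observed_states(aln, j, mask) if s is not None}
        if len(states) >= 2:
            n_variable += 1
    return aln.length, n_variable
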