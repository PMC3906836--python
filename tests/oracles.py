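"""Independent brute-force oracles used to check the implementation.

Everything here is written from the textbook definition, deliberately
without reusing any code path from the package: a Gotoh-style affine-gap
local alignment DP, per-window identity recounts, exhaustive Fitch
scoring by enumerating internal-node labelings, and a direct
minimum-change recount.
"""

from __future__ import annotations

from itertools import product

NEG = float("-inf")


def local_score_dp(a, b, score, gap_open, gap_extend):
    """Optimal local alignment score, affine gaps, O(nm) Gotoh DP.

    ``score(x, y)`` is the substitution score; a gap of length k costs
    ``gap_open + (k - 1) * gap_extend`` (the first gapped residue pays
    the open penalty).
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return max(best, 0.0)


def window_identity_recount(rows, start, w, alphabet="ACGT"):
    """Number of columns in [start, start+w) identical in all rows."""
    count = 0
    for j in range(start, start + w):
        col = {r[j] for r in rows}
        if len(col) == 1 and next(iter(col)) in alphabet:
            count += 1
    return count


def _tree_edges(tree, counter=None, edges=None, nodes=None):
    """Edge list of a nested-tuple tree; internal nodes get fresh ids."""
    if counter is None:
        counter, edges, nodes = [0], [], {}
    if isinstance(tree, str):
        return tree, edges, nodes
    counter[0] += 1
    me = f"__internal_{counter[0]}"
    nodes[me] = None
    for child in tree:
        cid, _, _ = _tree_edges(child, counter, edges, nodes)
        edges.append((me, cid))
    return me, edges, nodes


def fitch_enumerate(tree, leaf_state):
    """Minimum changes at one site by enumerating internal labelings.

    ``leaf_state`` maps leaf name to its state or None for missing.
    Internal nodes and missing leaves range over the observed states
    (an optimal unit-cost labeling never needs an unobserved state);
    a site with < 2 observed states costs 0.
    """
    observed = sorted({s for s in leaf_state.values() if s is not None})
    if len(observed) < 2:
        return 0
    root, edges, internals = _tree_edges(tree)
    free = list(internals) + [l for l, s in leaf_state.items() if s is None]
    fixed = {l: s for l, s in leaf_state.items() if s is not None}
    best = None
    for combo in product(observed, repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        cost = sum(1 for u, v in edges if assign[u] != assign[v])
        if best is None or cost < best:
            best = cost
    return best


def min_changes_recount(columns):
    """Sum over columns of (distinct non-missing states - 1), floored at 0."""
    total = 0
    for col in columns:
        states = {s for s in col if s is not None}
        total += max(len(states) - 1, 0)
    return total
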