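"""Independent brute-force oracles and exhaustive instance generators.

These deliberately avoid the library's algorithms: reconciliation is scored
by enumerating *all* valid species mappings, Dollo by enumerating loss-edge
subsets, and Fisher's test by enumerating all tables with the observed
margins.  They are shared by the unit/property tests and the acceptance
checks.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement
from math import comb

from phylofam.trees import SpeciesTree, TreeNode, make_gene_label

# ---------------------------------------------------------------------------
# exhaustive gene-tree enumeration (canonical, up to isomorphism)
# ---------------------------------------------------------------------------


def enumerate_shapes(leaf_species: tuple[str, ...]) -> set:
    """All rooted binary tree shapes over a species multiset, up to isomorphism.

    Trees are nested tuples: a leaf is a species string, an internal node a
    sorted pair of subtrees.
    """
    leaves = tuple(sorted(leaf_species))
    if len(leaves) == 1:
        return {leaves[0]}
    out = set()
    n = len(leaves)
    for r in range(1, n // 2 + 1):
        for idx in combinations(range(n), r):
            left = tuple(leaves[i] for i in idx)
            right = tuple(leaves[i] for i in range(n) if i not in idx)
            for lt in enumerate_shapes(left):
                for rt in enumerate_shapes(right):
                    out.add(tuple(sorted((lt, rt), key=repr)))
    return out


def shape_to_gene_tree(shape) -> TreeNode:
    counter = [0]

    def build(s) -> TreeNode:
        if isinstance(s, str):
            counter[0] += 1
            return TreeNode(make_gene_label(s, f"p{counter[0]}"))
        node = TreeNode()
        for child in s:
            node.add(build(child))
        return node

    return build(shape)


def enumerate_gene_trees(species: list[str], n_leaves: int):
    """Yield every gene tree (up to isomorphism) with n_leaves over species."""
    for multiset in combinations_with_replacement(sorted(species), n_leaves):
        for shape in sorted(enumerate_shapes(multiset), key=repr):
            yield shape_to_gene_tree(shape)


# ---------------------------------------------------------------------------
# brute-force duplication/loss reconciliation
# ---------------------------------------------------------------------------


def _subtree_of(stree: SpeciesTree, anc: int, desc: int) -> int:
    """Which child subtree of ``anc`` contains ``desc`` (-1 if desc == anc)."""
    if desc == anc:
        return -1
    while stree.parent[desc] != anc:
        desc = stree.parent[desc]
    return desc


def _mapping_cost(gtree: TreeNode, stree: SpeciesTree, mapping: dict) -> tuple[int, int]:
    # a node is a speciation only when its children map into *distinct*
    # child subtrees of its own mapping; otherwise it is a duplication
    dups = losses = 0
    for node in gtree.postorder():
        if node.is_leaf:
            continue
        mv = mapping[id(node)]
        sides = [_subtree_of(stree, mv, mapping[id(c)]) for c in node.children]
        is_speciation = -1 not in sides and sides[0] != sides[1]
        if not is_speciation:
            dups += 1
        for c in node.children:
            k = stree.depth[mapping[id(c)]] - stree.depth[mv]
            losses += k - 1 if is_speciation else k
    return dups, losses


def brute_force_reconcile(gtree: TreeNode, stree: SpeciesTree):
    """Minimum duplications/losses over *all* valid species mappings.

    A mapping assigns each internal gene node a species node that is an
    ancestor-or-equal of the LCA of its children's assignments.  Returns
    (min total cost, min duplications over mappings, min losses over
    mappings).
    """
    from phylofam.trees import split_gene_label

    nodes = list(gtree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    mapping: dict[int, int] = {}
    for n in nodes:
        if n.is_leaf:
            mapping[id(n)] = stree.index(split_gene_label(n.label)[0])

    best = [None, None, None]  # min total, min dups, min losses

    def assign(i: int) -> None:
        if i == len(internal):
            d, l = _mapping_cost(gtree, stree, mapping)
            if best[0] is None or d + l < best[0]:
                best[0] = d + l
            if best[1] is None or d < best[1]:
                best[1] = d
            if best[2] is None or l < best[2]:
                best[2] = l
            return
        v = internal[i]
        low = stree.lca_many(mapping[id(c)] for c in v.children)
        s = low
        while True:
            mapping[id(v)] = s
            assign(i + 1)
            if s == stree.root_index:
                break
            s = stree.parent[s]
        del mapping[id(v)]

    # postorder guarantees children assigned before parents
    internal.sort(key=lambda n: nodes.index(n))
    assign(0)
    return best[0], best[1], best[2]


# ---------------------------------------------------------------------------
# brute-force Dollo
# ---------------------------------------------------------------------------


def brute_force_dollo(stree: SpeciesTree, gain: int, present_species: frozenset) -> int:
    """Minimal number of loss edges explaining a presence pattern.

    Enumerates all subsets of species-tree edges below the gain node and
    returns the size of the smallest subset under which exactly the species
    in ``present_species`` (among leaves under the gain) survive.
    """
    below = [
        child
        for _, child in stree.edges()
        if stree.is_ancestor_or_equal(gain, child) and child != gain
    ]
    target = {
        leaf
        for leaf in stree.leaf_indices
        if stree.nodes[leaf].label in present_species
    }
    for size in range(len(below) + 1):
        for subset in combinations(below, size):
            lost = set(subset)
            surviving = set()
            for leaf in stree.leaf_indices:
                if not stree.is_ancestor_or_equal(gain, leaf):
                    continue
                i = leaf
                dead = False
                while i != gain:
                    if i in lost:
                        dead = True
                        break
                    i = stree.parent[i]
                if not dead:
                    surviving.add(leaf)
            if surviving == target:
                return size
    raise AssertionError("no loss placement explains the pattern")


# ---------------------------------------------------------------------------
# Fisher exact by enumeration
# ---------------------------------------------------------------------------


def fisher_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# hypergeometric tail by enumeration
# ---------------------------------------------------------------------------


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return total / comb(N, n)
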