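"""Equally weighted Wagner parsimony with ancestor-based intrinsic rooting.

The hypothetical ancestor participates in the search as an ordinary leaf
(the PAUP* ANCSTATES-with-included-ancestor usage); afterwards each minimal
tree is rooted on the branch where the ancestor attaches and the ancestor
leaf is pruned, producing an intrinsically rooted ingroup tree.  Reported
tree lengths are those of the search trees, i.e. they include the steps on
the ancestor's terminal branch.

Search strategies: ``exhaustive`` (complete enumeration by stepwise
insertion, all minimal trees), ``branch_and_bound`` (same enumeration with
an admissible incremental bound seeded by a greedy addition tree), and
``heuristic`` (random-addition replicates with TBR branch swapping; one
shortest tree kept per replicate, distinct minima pooled, MULTREES-style).
All tie-breaks are first-found under a generator seeded from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats as _sstats

from .matrix import ANCESTOR_NAME, CharacterMatrix, MISSING
from . import wagner
from .wagner import LeafData, attach_costs, edge_profiles, join_gaps

__all__ = [
    "SearchResult",
    "TreeStats",
    "search",
    "tree_length",
    "strict_consensus",
    "consistency_stats",
    "g1_statistic",
    "bootstrap",
]


# ---------------------------------------------------------------------------
# tuple-shaped trees (leaves are taxon indices)


def _min_leaf(tp) -> int:
    while not isinstance(tp, (int, np.integer)):
        tp = tp[0] if _min_leaf(tp[0]) <= _min_leaf(tp[1]) else tp[1]
    return int(tp)


def canonical(tp):
    """Sorted-children normal form; equal tuples <=> equal rooted topologies."""
    if isinstance(tp, (int, np.integer)):
        return int(tp)
    a = canonical(tp[0])
    b = canonical(tp[1])
    return (a, b) if _min_leaf(a) <= _min_leaf(b) else (b, a)


def leaf_context(tp, leaf: int):
    """The rest of the tree as seen from ``leaf``'s pendant edge.

    Returns a tuple rooted exactly at the leaf's attachment point, i.e. the
    ingroup tree rooted where the hypothetical ancestor joins it.
    """

    def rec(t, outside):
        if isinstance(t, (int, np.integer)):
            return outside if int(t) == leaf else None
        a, b = t
        res = rec(a, (outside, b))
        if res is not None:
            return res
        return rec(b, (outside, a))

    a, b = tp
    if isinstance(a, (int, np.integer)) and int(a) == leaf:
        return b
    if isinstance(b, (int, np.integer)) and int(b) == leaf:
        return a
    res = rec(a, b)
    if res is None:
        res = rec(b, a)
    if res is None:
        raise ValueError(f"leaf {leaf} not in tree")
    return res


def canonical_unrooted(tp):
    """Canonical form of the unrooted topology, rerooted on the pendant edge
    of the lowest-numbered leaf.  Preserves the full leaf set, so the result
    is itself a valid tree tuple."""
    ml = _min_leaf(tp)
    return (ml, canonical(leaf_context(tp, ml)))


def tuple_to_newick(tp, labels: list[str]) -> str:
    def rec(t):
        if isinstance(t, (int, np.integer)):
            lab = labels[int(t)]
            return f"'{lab}'" if any(ch in lab for ch in " (),:;") else lab
        return "(" + ",".join(rec(c) for c in t) + ")"

    return rec(tp) + ";"


def _tuple_to_arrays(tp, cap: int | None = None):
    """Flatten a tuple tree to (left, right, taxon, root) postorder arrays."""
    left: list[int] = []
    right: list[int] = []
    taxon: list[int] = []

    def build(t) -> int:
        if isinstance(t, (int, np.integer)):
            left.append(-1)
            right.append(-1)
            taxon.append(int(t))
        else:
            l = build(t[0])
            r = build(t[1])
            left.append(l)
            right.append(r)
            taxon.append(-1)
        return len(left) - 1

    root = build(tp)
    return (
        np.array(left, np.int32),
        np.array(right, np.int32),
        np.array(taxon, np.int32),
        root,
    )


def tuple_length(tp, ld: LeafData) -> int:
    if isinstance(tp, (int, np.integer)):
        return 0
    left, right, taxon, root = _tuple_to_arrays(tp)
    return wagner.tree_length_arrays(left, right, taxon, root, ld)


def _tuple_profiles(tp, ld: LeafData):
    """(length, edge_node_ids, ilo, ihi, imask, node_subtrees, node_contexts).

    Edges are represented by their lower node; the duplicate root edge is
    collapsed to the root's left child.
    """
    if isinstance(tp, (int, np.integer)):
        t = int(tp)
        ilo = ld.lo[[t]]
        ihi = ld.hi[[t]]
        imask = ld.mask[[t]]
        return 0, [0], ilo, ihi, imask, {0: t}, {0: None}
    left, right, taxon, root = _tuple_to_arrays(tp)
    length, ilo, ihi, imask = edge_profiles(left, right, taxon, root, ld)
    subs: dict[int, object] = {}
    ctxs: dict[int, object] = {}

    def collect(t) -> int:
        if isinstance(t, (int, np.integer)):
            node = collect.counter
            collect.counter += 1
            subs[node] = int(t)
            return node
        collect(t[0])
        collect(t[1])
        node = collect.counter
        collect.counter += 1
        subs[node] = t  # keep the original object: insertion matches by identity
        return node

    collect.counter = 0
    collect(tp)
    # contexts, preorder
    order = sorted(subs, reverse=True)  # root last-built = highest id
    ctxs[root] = None
    for v in order:
        if left[v] < 0:
            continue
        l, r = int(left[v]), int(right[v])
        if v == root:
            ctxs[l] = subs[r]
            ctxs[r] = subs[l]
        else:
            ctxs[l] = (ctxs[v], subs[r])
            ctxs[r] = (ctxs[v], subs[l])
    edges = [v for v in range(len(subs)) if v != root and v != int(right[root])]
    return length, edges, ilo, ihi, imask, subs, ctxs


# ---------------------------------------------------------------------------
# searches


@dataclass
class SearchResult:
    """Minimal trees plus bookkeeping from one parsimony search."""

    trees: list[dendropy.Tree]
    newicks: list[str]
    length: int
    strategy: str
    rooted: bool
    saturated: bool = False
    replicate_lengths: list[int] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.newicks)


def _greedy_addition(ld: LeafData, order: list[int], rng: np.random.Generator):
    """Stepwise addition tree; ties broken first-found on a shuffled edge order."""
    tp = (order[0], order[1])
    length = tuple_length(tp, ld)
    for t in order[2:]:
        _, edges, ilo, ihi, imask, subs, _ = _tuple_profiles(tp, ld)
        costs = attach_costs(ilo, ihi, imask, edges, ld, t)
        perm = rng.permutation(len(edges))
        best = perm[int(np.argmin(costs[perm]))]
        length += int(costs[best])
        tp = _insert_at_node(tp, subs, edges[best], t)
    return tp, tuple_length(tp, ld)


def _insert_at_node(tp, subs, node, leaf):
    """Rebuild ``tp`` with ``leaf`` attached on the edge above ``node``."""
    target = subs[node]

    done = [False]

    def rec(t):
        if done[0]:
            return t
        if t is target or (
            isinstance(t, (int, np.integer))
            and isinstance(target, (int, np.integer))
            and int(t) == int(target)
        ):
            done[0] = True
            return (t, leaf)
        if isinstance(t, (int, np.integer)):
            return t
        return (rec(t[0]), rec(t[1]))

    out = rec(tp)
    if not done[0]:  # pragma: no cover
        raise RuntimeError("edge not found during insertion")
    return out


def _enumerate(ld: LeafData, order: list[int], bound: int | None,
               max_trees: int, prune: bool):
    """DFS over stepwise-insertion space (each unrooted topology visited once).

    With ``prune`` this is branch and bound (the incremental length of a
    partial tree is an admissible lower bound); without it, exhaustive
    enumeration.  Returns (best_length, canonical tuples, saturated).
    """
    best: list[int] = [bound if bound is not None else (1 << 60)]
    found: dict[object, None] = {}
    saturated = [False]

    def record(tp, length):
        if length < best[0]:
            best[0] = length
            found.clear()
        if length == best[0]:
            if len(found) >= max_trees:
                saturated[0] = True
            else:
                found[canonical_unrooted(tp)] = None

    def expand(tp, length, k):
        if k == len(order):
            record(tp, length)
            return
        _, edges, ilo, ihi, imask, subs, _ = _tuple_profiles(tp, ld)
        costs = attach_costs(ilo, ihi, imask, edges, ld, order[k])
        for e_idx in np.argsort(costs, kind="stable"):
            new_len = length + int(costs[e_idx])
            if prune and new_len > best[0]:
                break  # costs sorted ascending: the rest are no better
            child = _insert_at_node(tp, subs, edges[e_idx], order[k])
            expand(child, new_len, k + 1)

    tp0 = (order[0], order[1])
    expand(tp0, tuple_length(tp0, ld), 2)
    return best[0], list(found.keys()), saturated[0]


def _tbr_scan(tp, ld: LeafData, rng: np.random.Generator, cur_len: int,
              equal_cap: int = 0):
    """Scan the full TBR neighborhood of ``tp``.

    Returns (best_tp, best_len, equals): the best neighbor (first-found
    among ties under a seeded bisection order) and, when ``equal_cap`` > 0,
    up to that many neighbors whose length equals ``cur_len`` (the plateau,
    for MULTREES-style swapping).  Plateau collection costs extra tuple
    surgery, so improvement-seeking scans request none.
    """
    _, edges, _, _, _, subs, ctxs = _tuple_profiles(tp, ld)
    best_len = None
    best_tp = None
    equals: list = []
    for v in rng.permutation(len(edges)):
        node = edges[int(v)]
        sub_tp = subs[node]
        ctx_tp = ctxs[node]
        if ctx_tp is None:
            continue
        len1, e1, ilo1, ihi1, imask1, subs1, ctxs1 = _tuple_profiles(sub_tp, ld)
        len2, e2, ilo2, ihi2, imask2, subs2, ctxs2 = _tuple_profiles(ctx_tp, ld)
        gaps = join_gaps(ilo1, ihi1, imask1, e1, ilo2, ihi2, imask2, e2)
        total = len1 + len2 + gaps
        k = int(np.argmin(total))
        cand = int(total.flat[k])
        if best_len is None or cand < best_len:
            i, j = divmod(k, gaps.shape[1])
            side1 = _reroot_component(subs1, ctxs1, e1[i])
            side2 = _reroot_component(subs2, ctxs2, e2[j])
            best_tp = (side1, side2)
            best_len = cand
            if best_len < cur_len:
                return best_tp, best_len, equals  # take first improvement
        if equal_cap and len(equals) < equal_cap:
            eq_i, eq_j = np.nonzero(total == cur_len)
            for i, j in zip(eq_i[: equal_cap - len(equals)], eq_j):
                side1 = _reroot_component(subs1, ctxs1, e1[int(i)])
                side2 = _reroot_component(subs2, ctxs2, e2[int(j)])
                equals.append((side1, side2))
    return best_tp, best_len, equals


def _reroot_component(subs, ctxs, node):
    """Component rerooted at the subdivision point of the edge above ``node``."""
    if ctxs[node] is None:  # single-leaf component or its root edge
        return subs[node]
    return (subs[node], ctxs[node])


def _swap_replicate(ld: LeafData, order: list[int], rng: np.random.Generator,
                    plateau_cap: int = 12):
    """One random-addition + TBR replicate with plateau swapping.

    TBR moves strictly downhill whenever possible; on a plateau, up to
    ``plateau_cap`` distinct equal-length trees are also swapped (MULTREES
    semantics), which lets the search escape local optima reachable through
    equally parsimonious rearrangements.
    """
    tp, length = _greedy_addition(ld, order, rng)
    while True:
        # downhill phase: first-improvement TBR moves
        while True:
            best_tp, best_len, _ = _tbr_scan(tp, ld, rng, length)
            if best_tp is not None and best_len < length:
                tp, length = best_tp, best_len
            else:
                break
        if plateau_cap < 2:
            return {canonical_unrooted(tp): tp}, length
        # plateau phase: swap equally parsimonious trees until one improves
        plateau = {canonical_unrooted(tp): tp}
        frontier = [tp]
        improved = False
        while frontier and not improved:
            t = frontier.pop()
            best_tp, best_len, equals = _tbr_scan(t, ld, rng, length, equal_cap=6)
            if best_tp is not None and best_len < length:
                tp, length = best_tp, best_len
                improved = True
                break
            for e in equals:
                key = canonical_unrooted(e)
                if key not in plateau and len(plateau) < plateau_cap:
                    plateau[key] = e
                    frontier.append(e)
        if not improved:
            return plateau, length


def _heuristic(ld: LeafData, n_leaves: int, n_reps: int, seed: int,
               max_trees: int, plateau_cap: int = 12):
    rng = np.random.default_rng(seed)
    pool: dict[object, None] = {}
    best_len = None
    rep_lengths = []
    saturated = False
    for _ in range(n_reps):
        order = [int(x) for x in rng.permutation(n_leaves)]
        plateau, length = _swap_replicate(ld, order, rng, plateau_cap)
        rep_lengths.append(length)
        if best_len is None or length < best_len:
            best_len = length
            pool = {}
        if length == best_len:
            for key in plateau:
                if len(pool) >= max_trees:
                    saturated = True
                    break
                pool[key] = None
    return best_len, list(pool.keys()), saturated, rep_lengths


def _to_rooted(tp, ld: LeafData, rooted: bool):
    """Root at the ancestor's attachment branch and prune the ancestor leaf."""
    if rooted:
        return leaf_context(tp, ld.ancestor_index)
    return tp


def _as_dendropy(newick: str, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=tns,
        rooting="force-rooted",
        preserve_underscores=True,
    )


def search(
    M: CharacterMatrix,
    strategy: str = "auto",
    n_reps: int = 10,
    seed: int = 1,
    include_ancestor: bool | None = None,
    max_trees: int = 10000,
    plateau_cap: int = 12,
) -> SearchResult:
    """Find minimal-length trees for a character matrix.

    With an ancestor row (default whenever the matrix has one) the returned
    trees are rooted on the ancestor's attachment branch with the ancestor
    pruned; reported length includes the ancestor's terminal branch.

    ``plateau_cap`` bounds MULTREES-style swapping of equally parsimonious
    trees per heuristic replicate (helps escape TBR islands on small
    problems; set < 2 to disable on large searches where random-addition
    replicates provide the diversity).
    """
    if include_ancestor is None:
        include_ancestor = M.ancestor is not None
    ld = LeafData(M, include_ancestor=include_ancestor)
    n = ld.n_leaves
    if n < 3:
        raise ValueError("need at least 3 leaves (including the ancestor)")
    if strategy == "auto":
        strategy = "exhaustive" if n <= 8 else (
            "branch_and_bound" if n <= 12 else "heuristic"
        )
    if strategy == "exhaustive" and n > 10:
        raise ValueError("exhaustive search is limited to 10 leaves")

    order = list(range(n))
    rep_lengths: list[int] = []
    if strategy == "exhaustive":
        best, tuples, saturated = _enumerate(ld, order, None, max_trees, False)
    elif strategy == "branch_and_bound":
        rng = np.random.default_rng(seed)
        _, ub = _greedy_addition(ld, order, rng)
        best, tuples, saturated = _enumerate(ld, order, ub, max_trees, True)
    elif strategy == "heuristic":
        best, tuples, saturated, rep_lengths = _heuristic(
            ld, n, n_reps, seed, max_trees, plateau_cap
        )
    else:
        raise ValueError(f"unknown search strategy {strategy!r}")

    rooted = bool(include_ancestor)
    labels = ld.names
    tns = dendropy.TaxonNamespace()
    newicks = []
    trees = []
    for tp in tuples:
        rtp = _to_rooted(tp, ld, rooted)
        nwk = tuple_to_newick(canonical(rtp) if rooted else canonical_unrooted(rtp), labels)
        newicks.append(nwk)
        trees.append(_as_dendropy(nwk, tns))
    # deterministic report order
    pairs = sorted(zip(newicks, trees), key=lambda p: p[0])
    newicks = [p[0] for p in pairs]
    trees = [p[1] for p in pairs]
    return SearchResult(
        trees=trees,
        newicks=newicks,
        length=int(best),
        strategy=strategy,
        rooted=rooted,
        saturated=saturated,
        replicate_lengths=rep_lengths,
        taxa=[t for t in labels if t != ANCESTOR_NAME] if rooted else list(labels),
    )


# ---------------------------------------------------------------------------
# lengths, consensus, statistics


def tree_length(tree: dendropy.Tree, M: CharacterMatrix,
                with_ancestor: bool = False) -> int:
    """Parsimony length of an arbitrary tree under the matrix costs.

    Ordered characters cost |i - j| (full Sankoff over the 62-state space);
    unordered characters use Fitch costs.  ``with_ancestor`` attaches the
    matrix ancestor row at the root, matching search-reported lengths.
    """
    return wagner.sankoff_length(tree, M, with_ancestor=with_ancestor)


def strict_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Strict consensus of rooted trees: clades present in every input."""
    if not trees:
        raise ValueError("need at least one tree")

    def clades(tree):
        out = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        return out

    leaf_sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    if len(set(leaf_sets)) != 1:
        raise ValueError("trees have different leaf sets")
    common = set.intersection(*(clades(t) for t in trees))
    common.add(leaf_sets[0])

    # laminar family -> nested newick
    ordered = sorted(common, key=len)
    parent: dict[frozenset, frozenset | None] = {}
    for i, c in enumerate(ordered):
        parent[c] = next((d for d in ordered[i + 1:] if c < d), None)

    children: dict[frozenset | None, list] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    for lf in leaf_sets[0]:
        enclosing = min((c for c in ordered if lf in c), key=len)
        children.setdefault(enclosing, []).append(lf)

    def build(c) -> str:
        kids = children.get(c, [])
        parts = []
        for k in sorted(kids, key=lambda x: x if isinstance(x, str) else min(x)):
            if isinstance(k, str):
                parts.append(k)
            else:
                parts.append(build(k))
        return "(" + ",".join(parts) + ")"

    root = leaf_sets[0]
    nwk = build(root) + ";"
    return _as_dendropy(nwk, dendropy.TaxonNamespace())


@dataclass
class TreeStats:
    """Homoplasy and signal statistics of a set of minimal trees."""

    length: int
    n_min_trees: int
    ci_with: float
    ci_without: float
    ri: float
    rc: float
    g1: float | None = None
    bootstrap: dict[tuple[str, ...], float] | None = None


def _char_min_max_steps(M: CharacterMatrix, include_ancestor: bool):
    """Per-character minimum (m) and star-tree maximum (g) step counts."""
    rows = M.values
    if include_ancestor and M.ancestor is not None:
        rows = np.vstack([rows, M.ancestor[None, :]])
    m = np.zeros(M.n_chars, np.int64)
    g = np.zeros(M.n_chars, np.int64)
    for k, c in enumerate(M.chars):
        col = rows[:, k]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        if c.ordered:
            m[k] = int(col.max() - col.min())
            med = int(np.median(col))
            g[k] = int(np.abs(col - med).sum())
        else:
            _, counts = np.unique(col, return_counts=True)
            m[k] = len(counts) - 1
            g[k] = int(col.size - counts.max())
    return m, g


def consistency_stats(
    trees_or_length, M: CharacterMatrix, include_ancestor: bool | None = None
) -> TreeStats:
    """CI (with and without uninformative characters), RI and RC.

    CI = m/s with m the sum of per-character state ranges and s the tree
    length; RI = (g - s)/(g - m) with g the star-tree (worst-case) length;
    RC = CI x RI.  A character is parsimony-uninformative when its best and
    worst attainable lengths coincide (g_i == m_i), in which case it
    contributes equally to every topology.
    """
    if include_ancestor is None:
        include_ancestor = M.ancestor is not None
    if isinstance(trees_or_length, (int, np.integer)):
        s = int(trees_or_length)
        n_trees = 1
    else:
        trees = list(trees_or_length)
        s = tree_length(trees[0], M, with_ancestor=include_ancestor)
        n_trees = len(trees)
    m, g = _char_min_max_steps(M, include_ancestor)
    m_tot = int(m.sum())
    uninf = m == g
    m_uninf = int(m[uninf].sum())
    ci = m_tot / s if s > 0 else 1.0
    s_wo = s - m_uninf
    m_wo = m_tot - m_uninf
    ci_wo = m_wo / s_wo if s_wo > 0 else 1.0
    g_tot = int(g.sum())
    ri = (g_tot - s) / (g_tot - m_tot) if g_tot > m_tot else 1.0
    return TreeStats(
        length=s,
        n_min_trees=n_trees,
        ci_with=ci,
        ci_without=ci_wo,
        ri=ri,
        rc=ci * ri,
    )


def _random_topology(n: int, rng: np.random.Generator):
    tp = (0, 1)
    n_edges = 1
    for t in range(2, n):
        # uniform over edges = uniform over labeled topologies
        target = int(rng.integers(n_edges))
        tp = _insert_at_edge_index(tp, target, t)
        n_edges += 2
    return tp


def _insert_at_edge_index(tp, target: int, leaf: int):
    """Insert on the ``target``-th unrooted edge.

    Edge 0 is the root edge (between the two top-level subtrees); edges
    1..2k-4 are the parent edges of proper subtrees below the top level, in
    preorder.  Enumerating this way visits each of the 2k-3 unrooted edges
    exactly once, so a uniform ``target`` yields uniform random topologies.
    """
    if target == 0:
        return (tp, leaf)
    counter = [0]
    done = [False]

    def walk(t, count_self: bool):
        if done[0]:
            return t
        if count_self:
            counter[0] += 1
            if counter[0] == target:
                done[0] = True
                return (t, leaf)
        if isinstance(t, (int, np.integer)):
            return t
        return (walk(t[0], True), walk(t[1], True))

    out = (walk(tp[0], False), walk(tp[1], False))
    if not done[0]:  # pragma: no cover
        raise ValueError(f"edge index {target} out of range")
    return out


def g1_statistic(
    M: CharacterMatrix,
    n_random: int = 10000,
    seed: int = 1,
    include_ancestor: bool | None = None,
) -> float:
    """Skewness (g1) of the tree-length distribution over random topologies.

    Lengths are computed on ``n_random`` uniformly sampled unrooted binary
    topologies; strongly negative g1 indicates hierarchical structure in the
    data.  Raises on a zero-variance length distribution.
    """
    if n_random < 100:
        raise ValueError("need at least 100 random trees")
    if include_ancestor is None:
        include_ancestor = M.ancestor is not None
    ld = LeafData(M, include_ancestor=include_ancestor)
    rng = np.random.default_rng(seed)
    lengths = np.empty(n_random)
    for i in range(n_random):
        tp = _random_topology(ld.n_leaves, rng)
        lengths[i] = tuple_length(tp, ld)
    if np.ptp(lengths) == 0:
        raise ValueError("tree-length distribution has zero variance; g1 undefined")
    return float(_sstats.skew(lengths, bias=True))


def bootstrap(
    M: CharacterMatrix,
    reporting_tree: dendropy.Tree,
    n_reps: int = 1000,
    seed: int = 1,
    include_ancestor: bool | None = None,
) -> dict[tuple[str, ...], float]:
    """Clade support by fast stepwise-addition bootstrap.

    Each replicate resamples characters with replacement and builds one tree
    by greedy stepwise addition with a random taxon order (no branch
    swapping).  Support is the percentage of replicates containing each
    clade of the reporting tree (clades measured on the ancestor-rooted
    topology).
    """
    if n_reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if include_ancestor is None:
        include_ancestor = M.ancestor is not None
    ld = LeafData(M, include_ancestor=include_ancestor)
    rng = np.random.default_rng(seed)

    def clades_of(tree) -> set[frozenset]:
        out = set()
        for node in tree.postorder_internal_node_iter():
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out.add(leaves)
        return out

    report_clades = {
        c
        for c in clades_of(reporting_tree)
        if 1 < len(c) < len(reporting_tree.leaf_nodes())
    }
    tally = {c: 0 for c in report_clades}
    labels = ld.names
    for _ in range(n_reps):
        ldb = ld.resample_columns(rng)
        order = [int(x) for x in rng.permutation(ld.n_leaves)]
        tp, _ = _greedy_addition(ldb, order, rng)
        rtp = _to_rooted(tp, ld, include_ancestor)
        rep = _clade_sets(rtp, labels)
        for c in report_clades:
            if c in rep:
                tally[c] += 1
    return {
        tuple(sorted(c)): 100.0 * k / n_reps for c, k in tally.items()
    }


def _clade_sets(tp, labels) -> set[frozenset]:
    out: set[frozenset] = set()

    def rec(t) -> frozenset:
        if isinstance(t, (int, np.integer)):
            return frozenset([labels[int(t)]])
        s = rec(t[0]) | rec(t[1])
        out.add(s)
        return s

    rec(tp)
    return out
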