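"""Low-level Wagner/Fitch machinery for parsimony on binary trees.

Ordered (linear-cost) characters use Farris interval propagation; unordered
characters (aligned sequence columns) use Fitch state sets held as 64-bit
masks.  The central identity used throughout the search code is that for
trees T1, T2 joined by a new branch between subdivision points on edges e1
and e2::

    len(join) = len(T1) + len(T2) + sum_c gap(I1(e1, c), I2(e2, c))

where ``I(e, c)`` is the state interval (or Fitch set) of the tree rooted at
edge ``e``.  This follows from the rooting-invariance of parsimony length
and makes stepwise addition, branch and bound, and TBR rearrangement exact
at O(taxa x characters) per evaluated tree.  A full Sankoff dynamic program
(:func:`sankoff_length`) over the complete 62-state space serves as the
independent slow path for arbitrary, possibly multifurcating trees.

Trees are flat arrays (``left``, ``right``, ``taxon``, capacity 2N-1); the
kernel is JIT-compiled with numba when available.
"""

from __future__ import annotations

import numpy as np

from .matrix import MISSING, CharacterMatrix, ANCESTOR_NAME

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _compile(fn):
        return _njit(cache=True)(fn)

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    def _compile(fn):
        return fn

    HAVE_NUMBA = False

MAX_ORDERED = 61  # top of the alphanumeric state alphabet
_FULL_MASK = np.uint64((1 << 62) - 1)


class LeafData:
    """Per-matrix leaf encodings for the parsimony kernels.

    Ordered characters become degenerate intervals (missing -> [0, 61]);
    unordered characters become Fitch bitmasks (missing -> all states).
    The hypothetical ancestor, when present, is appended as the last row
    under the name ``ANC``.
    """

    def __init__(self, M: CharacterMatrix, include_ancestor: bool = True):
        ordered_cols = [k for k, c in enumerate(M.chars) if c.ordered]
        unordered_cols = [k for k, c in enumerate(M.chars) if not c.ordered]
        rows = M.values
        names = list(M.taxa)
        if include_ancestor:
            if M.ancestor is None:
                raise ValueError("matrix has no ancestor row to include")
            rows = np.vstack([rows, M.ancestor[None, :]])
            names.append(ANCESTOR_NAME)
        n = rows.shape[0]
        ov = rows[:, ordered_cols].astype(np.int64)
        self.lo = np.where(ov == MISSING, 0, ov)
        self.hi = np.where(ov == MISSING, MAX_ORDERED, ov)
        uv = rows[:, unordered_cols].astype(np.int64)
        mask = np.left_shift(np.uint64(1), uv.clip(0).astype(np.uint64))
        self.mask = np.where(uv == MISSING, _FULL_MASK, mask).astype(np.uint64)
        self.names = names
        self.n_leaves = n
        self.n_ordered = len(ordered_cols)
        self.n_unordered = len(unordered_cols)
        self.ancestor_index = n - 1 if include_ancestor else None

    def resample_columns(self, rng: np.random.Generator) -> "LeafData":
        """Bootstrap resample of character columns (with replacement)."""
        out = object.__new__(LeafData)
        total = self.n_ordered + self.n_unordered
        pick = rng.integers(0, total, size=total)
        o_pick = pick[pick < self.n_ordered]
        u_pick = pick[pick >= self.n_ordered] - self.n_ordered
        out.lo = self.lo[:, o_pick]
        out.hi = self.hi[:, o_pick]
        out.mask = self.mask[:, u_pick]
        out.names = self.names
        out.n_leaves = self.n_leaves
        out.n_ordered = len(o_pick)
        out.n_unordered = len(u_pick)
        out.ancestor_index = self.ancestor_index
        return out


def _profiles_py(left, right, taxon, root, llo, lhi, lmask, ilo, ihi, imask,
                 want_edges):
    """Down-pass length plus (optionally) per-edge Farris/Fitch profiles.

    ``ilo/ihi/imask`` are filled, for every non-root node v, with the state
    interval of the whole tree rooted on the edge above v.
    """
    cap = left.shape[0]
    Co = llo.shape[1]
    Cu = lmask.shape[1]
    order = np.empty(cap, np.int32)
    stack = np.empty(cap, np.int32)
    ns = 1
    stack[0] = root
    n_order = 0
    while ns > 0:
        ns -= 1
        v = stack[ns]
        order[n_order] = v
        n_order += 1
        if left[v] >= 0:
            stack[ns] = left[v]
            ns += 1
            stack[ns] = right[v]
            ns += 1

    dlo = np.empty((cap, Co), np.int64)
    dhi = np.empty((cap, Co), np.int64)
    dmask = np.empty((cap, Cu), np.uint64)
    total = 0
    for idx in range(n_order - 1, -1, -1):
        v = order[idx]
        t = taxon[v]
        if t >= 0:
            for c in range(Co):
                dlo[v, c] = llo[t, c]
                dhi[v, c] = lhi[t, c]
            for c in range(Cu):
                dmask[v, c] = lmask[t, c]
        else:
            l = left[v]
            r = right[v]
            for c in range(Co):
                nl = max(dlo[l, c], dlo[r, c])
                nh = min(dhi[l, c], dhi[r, c])
                if nl > nh:
                    total += nl - nh
                    dlo[v, c] = nh
                    dhi[v, c] = nl
                else:
                    dlo[v, c] = nl
                    dhi[v, c] = nh
            for c in range(Cu):
                inter = dmask[l, c] & dmask[r, c]
                if inter == np.uint64(0):
                    total += 1
                    dmask[v, c] = dmask[l, c] | dmask[r, c]
                else:
                    dmask[v, c] = inter

    if want_edges:
        clo = np.empty((cap, Co), np.int64)
        chi = np.empty((cap, Co), np.int64)
        cmask = np.empty((cap, Cu), np.uint64)
        for idx in range(n_order):
            v = order[idx]
            if left[v] < 0:
                continue
            l = left[v]
            r = right[v]
            if v == root:
                for c in range(Co):
                    clo[l, c] = dlo[r, c]
                    chi[l, c] = dhi[r, c]
                    clo[r, c] = dlo[l, c]
                    chi[r, c] = dhi[l, c]
                for c in range(Cu):
                    cmask[l, c] = dmask[r, c]
                    cmask[r, c] = dmask[l, c]
            else:
                for c in range(Co):
                    a1 = clo[v, c]
                    b1 = chi[v, c]
                    # context of left child: combine(context(v), D(right))
                    nl = max(a1, dlo[r, c])
                    nh = min(b1, dhi[r, c])
                    if nl > nh:
                        clo[l, c] = nh
                        chi[l, c] = nl
                    else:
                        clo[l, c] = nl
                        chi[l, c] = nh
                    nl = max(a1, dlo[l, c])
                    nh = min(b1, dhi[l, c])
                    if nl > nh:
                        clo[r, c] = nh
                        chi[r, c] = nl
                    else:
                        clo[r, c] = nl
                        chi[r, c] = nh
                for c in range(Cu):
                    inter = cmask[v, c] & dmask[r, c]
                    cmask[l, c] = (cmask[v, c] | dmask[r, c]) if inter == np.uint64(0) else inter
                    inter = cmask[v, c] & dmask[l, c]
                    cmask[r, c] = (cmask[v, c] | dmask[l, c]) if inter == np.uint64(0) else inter
        for idx in range(n_order):
            v = order[idx]
            if v == root:
                continue
            for c in range(Co):
                nl = max(dlo[v, c], clo[v, c])
                nh = min(dhi[v, c], chi[v, c])
                if nl > nh:
                    ilo[v, c] = nh
                    ihi[v, c] = nl
                else:
                    ilo[v, c] = nl
                    ihi[v, c] = nh
            for c in range(Cu):
                inter = dmask[v, c] & cmask[v, c]
                imask[v, c] = (dmask[v, c] | cmask[v, c]) if inter == np.uint64(0) else inter
    return total


_profiles = _compile(_profiles_py)

_EMPTY_I = np.empty((0, 0), np.int64)
_EMPTY_M = np.empty((0, 0), np.uint64)


def tree_length_arrays(left, right, taxon, root, ld: LeafData) -> int:
    """Exact Wagner+Fitch length of a binary array-tree."""
    return int(
        _profiles(
            left, right, taxon, root, ld.lo, ld.hi, ld.mask,
            _EMPTY_I, _EMPTY_I, _EMPTY_M, False,
        )
    )


def edge_profiles(left, right, taxon, root, ld: LeafData):
    """Length plus per-node edge profiles (ilo, ihi, imask)."""
    cap = left.shape[0]
    ilo = np.empty((cap, ld.n_ordered), np.int64)
    ihi = np.empty((cap, ld.n_ordered), np.int64)
    imask = np.empty((cap, ld.n_unordered), np.uint64)
    total = _profiles(
        left, right, taxon, root, ld.lo, ld.hi, ld.mask, ilo, ihi, imask, True
    )
    return int(total), ilo, ihi, imask


def attach_costs(ilo, ihi, imask, edges, ld: LeafData, leaf: int) -> np.ndarray:
    """Extra steps incurred by attaching ``leaf`` on each candidate edge."""
    e = np.asarray(edges, np.int64)
    gap = np.maximum(ilo[e], ld.lo[leaf]) - np.minimum(ihi[e], ld.hi[leaf])
    cost = np.maximum(gap, 0).sum(axis=1)
    if ld.n_unordered:
        cost = cost + ((imask[e] & ld.mask[leaf]) == 0).sum(axis=1)
    return cost


def join_gaps(ilo1, ihi1, imask1, e1, ilo2, ihi2, imask2, e2) -> np.ndarray:
    """Gap matrix (len(e1) x len(e2)) for reconnecting two bisection halves."""
    a1 = np.asarray(e1, np.int64)
    a2 = np.asarray(e2, np.int64)
    lo = np.maximum(ilo1[a1][:, None, :], ilo2[a2][None, :, :])
    hi = np.minimum(ihi1[a1][:, None, :], ihi2[a2][None, :, :])
    g = np.maximum(lo - hi, 0).sum(axis=2)
    if imask1.shape[1]:
        inter = imask1[a1][:, None, :] & imask2[a2][None, :, :]
        g = g + (inter == 0).sum(axis=2)
    return g


# ---------------------------------------------------------------------------
# full Sankoff DP: slow, exact on arbitrary (multifurcating) trees


def _min_plus_linear(cost: np.ndarray) -> np.ndarray:
    """min_t (cost[t] + |s - t|) for every s, via two sweeps."""
    out = cost.copy()
    for s in range(1, out.shape[0]):
        np.minimum(out[s], out[s - 1] + 1, out=out[s])
    for s in range(out.shape[0] - 2, -1, -1):
        np.minimum(out[s], out[s + 1] + 1, out=out[s])
    return out


def _min_plus_uniform(cost: np.ndarray) -> np.ndarray:
    """min_t (cost[t] + [s != t]) for unordered characters."""
    best = cost.min(axis=0)
    return np.minimum(cost, best[None, :] + 1)


def sankoff_length(
    tree, M: CharacterMatrix, with_ancestor: bool = False
) -> int:
    """Parsimony length of an arbitrary rooted tree (polytomies allowed).

    ``tree`` is a dendropy tree whose leaf labels equal ``M.taxa``.  With
    ``with_ancestor=True`` the matrix ancestor row is attached at the root,
    reproducing the length of the search tree from which the ancestor leaf
    was pruned.
    """
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_names != set(M.taxa):
        missing = leaf_names ^ set(M.taxa)
        raise ValueError(f"tree leaves do not match matrix taxa: {sorted(missing)[:4]}")
    idx = {t: i for i, t in enumerate(M.taxa)}

    n_states = MAX_ORDERED + 1
    INF = np.int64(1 << 30)
    ordered_cols = [k for k, c in enumerate(M.chars) if c.ordered]
    unordered_cols = [k for k, c in enumerate(M.chars) if not c.ordered]

    def leaf_cost(row: np.ndarray, cols: list[int]) -> np.ndarray:
        cost = np.full((n_states, len(cols)), INF)
        for j, k in enumerate(cols):
            v = row[k]
            if v == MISSING:
                cost[:, j] = 0
            else:
                cost[v, j] = 0
        return cost

    total = 0
    memo: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = M.values[idx[node.taxon.label]]
            memo[id(node)] = (
                leaf_cost(row, ordered_cols),
                leaf_cost(row, unordered_cols),
            )
        else:
            oc = np.zeros((n_states, len(ordered_cols)), np.int64)
            uc = np.zeros((n_states, len(unordered_cols)), np.int64)
            for ch in node.child_nodes():
                co, cu = memo.pop(id(ch))
                oc += _min_plus_linear(co)
                uc += _min_plus_uniform(cu)
            memo[id(node)] = (oc, uc)
    oc, uc = memo[id(tree.seed_node)]
    if with_ancestor:
        if M.ancestor is None:
            raise ValueError("matrix has no ancestor row")
        anc = M.ancestor
        for j, k in enumerate(ordered_cols):
            v = anc[k]
            if v != MISSING:
                oc[:, j] += np.abs(np.arange(n_states) - v)
        for j, k in enumerate(unordered_cols):
            v = anc[k]
            if v != MISSING:
                uc[:, j] += (np.arange(n_states) != v).astype(np.int64)
    total = int(oc.min(axis=0).sum() + uc.min(axis=0).sum())
    return total
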