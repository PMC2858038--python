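"""Synthetic molecules and matrices with known ground truth.

The generator emulates the polarization model under which the real matrices
are coded: stem characters start at a maximal ancestral state and erode by
a downward-biased bounded random walk; loop characters start at 0 and grow;
substructures are *accreted* in a known order along the trunk of the true
tree (a substructure born late exists only in lineages diverging after its
birth, and is coded 0 elsewhere); lineages may additionally lose a
substructure outright.  Because the accretion order is known, the full
pipeline (matrix -> transposed matrix -> tree of substructures -> nd) can be
scored against the truth, and reversed-polarity analyses can be compared
for parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .matrix import CharacterDef, CharacterMatrix
from .structure import HomologyScheme, SecondaryStructure, parse_structure

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_matrix",
    "simulate_molecules",
    "synthetic_scheme",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic replicate.

    Defaults follow the low-noise regime used throughout the analyses: 20
    molecules, 30 stem characters accreted along the trunk of a Yule tree,
    ~0.2 expected state changes per character per branch with a strong
    erosive bias, and a small per-branch chance of outright substructure
    loss.
    """

    n_taxa: int = 20
    n_stem_chars: int = 30
    n_loop_chars: int = 0
    max_state: int = 12
    birth_rate: float = 1.0
    change_rate: float = 0.2
    drift: float = 0.8  # P(step toward the derived direction)
    loss_prob: float = 0.02
    accretion_schedule: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not (1 <= self.max_state <= 61):
            raise ValueError("max_state must be in 1..61")
        if self.n_loop_chars > self.n_stem_chars:
            raise ValueError(
                "each loop character is the hairpin of a stem; "
                "n_loop_chars cannot exceed n_stem_chars"
            )
        for name in ("birth_rate", "change_rate", "loss_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_chars(self) -> int:
        return self.n_stem_chars + self.n_loop_chars


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    newick: str
    birth_position: dict[str, int]  # char_id -> trunk node index (0 = root)
    accretion_rank: dict[str, int]  # char_id -> birth order (ties share rank)
    branch_changes: dict[tuple[str, ...], int] = field(default_factory=dict)


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """A Yule (pure-birth) tree with ``n_taxa`` leaves, labelled t1..tn."""
    rng = np.random.default_rng([config.seed, 0])
    next_leaf = [0]

    class _N:
        __slots__ = ("children", "edge")

        def __init__(self):
            self.children: list[_N] = []
            self.edge = 0.0

    root = _N()
    tips = [_N(), _N()]
    root.children = list(tips)
    while len(tips) < config.n_taxa:
        rate = config.birth_rate * len(tips) or 1.0
        dt = rng.exponential(1.0 / rate)
        for t in tips:
            t.edge += dt
        k = int(rng.integers(len(tips)))
        split = tips.pop(k)
        split.children = [_N(), _N()]
        tips.extend(split.children)
    dt = rng.exponential(1.0 / (config.birth_rate * len(tips) or 1.0))
    for t in tips:
        t.edge += dt

    labels = iter(f"t{i + 1}" for i in range(config.n_taxa))

    def nwk(n: _N) -> str:
        if not n.children:
            return f"{next(labels)}:{n.edge:.6f}"
        inner = ",".join(nwk(c) for c in n.children)
        return f"({inner}):{n.edge:.6f}"

    text = nwk(root) + ";"
    return dendropy.Tree.get(
        data=text, schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )


def _char_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    """(char_id, role) in matrix column order: P_i.len, then its L_i.len."""
    out = []
    for i in range(1, config.n_stem_chars + 1):
        out.append((f"P{i}.len", "stem"))
        if i <= config.n_loop_chars:
            out.append((f"L{i}.len", "loop"))
    return out


def _trunk(tree: dendropy.Tree) -> list:
    """Internal nodes from the root to the deepest leaf (most nodes)."""
    best_leaf = None
    best_depth = -1
    for leaf in tree.leaf_node_iter():
        d = 0
        node = leaf.parent_node
        while node is not None:
            d += 1
            node = node.parent_node
        if d > best_depth:
            best_depth = d
            best_leaf = leaf
    path = []
    node = best_leaf.parent_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    return list(reversed(path))  # root first


def simulate_matrix(
    config: SimulationConfig, tree: dendropy.Tree
) -> tuple[CharacterMatrix, GroundTruth]:
    """Evolve characters on the tree under the accretion/polarization model.

    Returns the molecules x characters matrix (no ancestor row attached) and
    the ground truth.  A stem eroded or lost to state 0 drags its hairpin
    loop to 0 as well, so every matrix is realisable as actual molecules.
    """
    rng = np.random.default_rng([config.seed, 1])
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise ValueError("tree must have at least 4 leaves")
    trunk = _trunk(tree)
    m = len(trunk)
    ids = _char_ids(config)
    n_chars = len(ids)

    if config.accretion_schedule is not None:
        if len(config.accretion_schedule) != n_chars:
            raise ValueError("accretion schedule length must equal total characters")
        births = list(config.accretion_schedule)
        if any(b >= m or b < 0 for b in births):
            raise ValueError(
                f"accretion schedule exceeds tree depth ({m} trunk nodes)"
            )
    else:
        # stems spread evenly along the trunk in order; each loop is born
        # with its host stem
        stem_births = [
            (i * m) // config.n_stem_chars for i in range(config.n_stem_chars)
        ]
        births = []
        for cid, role in ids:
            i = int(cid[1:].split(".")[0]) - 1
            births.append(stem_births[i])

    trunk_index = {id(node): k for k, node in enumerate(trunk)}
    birth_at: dict[int, list[int]] = {}
    for c, b in enumerate(births):
        birth_at.setdefault(b, []).append(c)

    roles = [role for _, role in ids]
    states = np.zeros(n_chars, np.int64)
    active = np.zeros(n_chars, bool)
    rows: dict[str, np.ndarray] = {}
    branch_changes: dict[tuple[str, ...], int] = {}

    def born(state_vec, active_vec, chars):
        for c in chars:
            active_vec[c] = True
            state_vec[c] = config.max_state if roles[c] == "stem" else 0

    def evolve_branch(state_vec, active_vec, clade_key):
        changed = 0
        for c in np.flatnonzero(active_vec):
            if config.loss_prob and rng.random() < config.loss_prob:
                changed += int(abs(state_vec[c]))
                active_vec[c] = False
                state_vec[c] = 0
                continue
            n_steps = rng.poisson(config.change_rate)
            for _ in range(n_steps):
                toward_derived = rng.random() < config.drift
                if roles[c] == "stem":
                    delta = -1 if toward_derived else 1
                else:
                    delta = 1 if toward_derived else -1
                s = state_vec[c] + delta
                s = max(0, min(config.max_state, s))  # reflecting bounds
                if s != state_vec[c]:
                    changed += 1
                state_vec[c] = s
        branch_changes[clade_key] = changed

    def clade_key(node) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))

    def walk(node, state_vec, active_vec):
        k = trunk_index.get(id(node))
        if k is not None:
            born(state_vec, active_vec, birth_at.get(k, []))
        if node.is_leaf():
            rows[node.taxon.label] = state_vec.copy()
            return
        for child in node.child_nodes():
            sv = state_vec.copy()
            av = active_vec.copy()
            evolve_branch(sv, av, clade_key(child))
            walk(child, sv, av)

    walk(tree.seed_node, states, active)

    values = np.stack([rows[t] for t in leaves])
    # a hairpin cannot outlive its stem
    for col, (cid, role) in enumerate(ids):
        if role != "loop":
            continue
        stem_col = next(
            j for j, (sid, r) in enumerate(ids) if r == "stem" and sid[1:] == cid[1:]
        )
        values[values[:, stem_col] == 0, col] = 0

    chars = [
        CharacterDef(
            cid,
            "stabilizing" if role == "stem" else "destabilizing",
            "none",
            "stem_bp" if role == "stem" else "loop_nt",
        )
        for cid, role in ids
    ]
    M = CharacterMatrix(leaves, chars, values.astype(np.int16))

    order = sorted(set(births))
    rank_of = {b: r for r, b in enumerate(order)}
    truth = GroundTruth(
        newick=tree.as_string(schema="newick").strip(),
        birth_position={cid: b for (cid, _), b in zip(ids, births)},
        accretion_rank={cid: rank_of[b] for (cid, _), b in zip(ids, births)},
        branch_changes=branch_changes,
    )
    return M, truth


# ---------------------------------------------------------------------------
# molecule realisation


def synthetic_scheme(n_stems: int, n_loops: int = 0) -> HomologyScheme:
    """Homology scheme matching the generator's P/L labelling."""
    universe: list[str] = []
    kinds: dict[str, str] = {}
    for i in range(1, n_stems + 1):
        universe.append(f"P{i}")
        kinds[f"P{i}"] = "stem"
        if i <= n_loops:
            universe.append(f"L{i}")
            kinds[f"L{i}"] = "hairpin"
    return HomologyScheme(tuple(universe), kinds)


def simulate_molecules(
    M: CharacterMatrix, scheme: HomologyScheme | None = None
) -> tuple[list[SecondaryStructure], dict[str, list[tuple[int, int, str]]]]:
    """Realise a matrix as dot-bracket molecules plus homology annotation.

    Each stem character P_i becomes a stem-hairpin module (G:C pairs with an
    A-loop of the matching L_i length, or a blunt helix when the matrix has
    no loop partner); state-0 substructures emit nothing.  Decomposing,
    labelling and re-coding the molecules reproduces the matrix exactly.
    """
    stems: list[str] = []
    loop_of: dict[str, str] = {}
    for c in M.chars:
        root, _, metric = c.char_id.partition(".")
        if c.metric == "stem_bp":
            stems.append(root)
        elif root.startswith("L"):
            loop_of["P" + root[1:]] = c.char_id
    col = {c.char_id: k for k, c in enumerate(M.chars)}

    structures = []
    annotation: dict[str, list[tuple[int, int, str]]] = {}
    for r, taxon in enumerate(M.taxa):
        seq: list[str] = []
        db: list[str] = []
        ann: list[tuple[int, int, str]] = []
        for p_lab in stems:
            s_len = int(M.values[r, col[f"{p_lab}.len"]])
            if s_len == 0:
                continue
            l_id = loop_of.get(p_lab)
            l_len = int(M.values[r, col[l_id]]) if l_id else 0
            start = len(seq)
            seq.extend("G" * s_len)
            db.extend("(" * s_len)
            if l_len:
                ann.append((start + s_len, start + s_len + l_len - 1, l_id.split(".")[0]))
                seq.extend("A" * l_len)
                db.extend("." * l_len)
            seq.extend("C" * s_len)
            db.extend(")" * s_len)
            end = len(seq) - 1
            ann.append((start, start + s_len - 1, p_lab))
            ann.append((end - s_len + 1, end, p_lab))
        if not seq:
            raise ValueError(f"taxon {taxon!r} realises a zero-length molecule")
        record = f">{taxon}\n{''.join(seq)}\n{''.join(db)}\n"
        structures.append(parse_structure(record, "dotbracket"))
        annotation[taxon] = ann
    return structures, annotation
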