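"""RNA secondary structures and their decomposition into substructures.

A molecule is held as a sequence plus a set of base pairs (pseudoknots
allowed).  :func:`decompose` cuts the molecule into typed substructures --
stems, hairpin loops, bulges/internal loops, multiloop segments, joints and
free ends -- such that every residue belongs to exactly one substructure.
:func:`label_substructures` attaches canonical homology labels (P-numbering)
from a :class:`HomologyScheme` so molecules can be compared column-wise.

Coordinates are 0-based closed intervals internally; CT/bpseq files and
annotation files are 1-based on disk and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SecondaryStructure",
    "Substructure",
    "HomologyScheme",
    "StructureParseError",
    "StructureValidationError",
    "LabelingError",
    "parse_structure",
    "read_structures",
    "write_dotbracket",
    "decompose",
    "label_substructures",
    "read_annotation",
]

STEM_KINDS = frozenset({"stem"})
LOOP_KINDS = frozenset(
    {"hairpin", "bulge", "internal_loop", "multiloop_segment", "free_end", "joint"}
)
ALL_KINDS = STEM_KINDS | LOOP_KINDS

#: bracket alphabets for pseudoknot layers in dot-bracket notation
#: (letter layers Aa..Dd for deeply knotted structures, as in extended .dbn)
_OPENERS = "([{<ABCD"
_CLOSERS = ")]}>abcd"


class StructureParseError(ValueError):
    """Malformed structure text (reports line/column where known)."""


class StructureValidationError(ValueError):
    """Structurally invalid input (e.g. a base paired twice)."""


class LabelingError(ValueError):
    """Annotation/label conflicts during homology labeling."""


@dataclass(frozen=True)
class SecondaryStructure:
    """One molecule: sequence plus base-pair set, with taxon metadata.

    ``pairs`` holds 0-based ``(i, j)`` tuples with ``i < j``; crossing pairs
    (pseudoknots) are permitted and are written out on separate bracket
    layers.
    """

    molecule_id: str
    sequence: str
    pairs: frozenset[tuple[int, int]]
    superkingdom: str | None = None
    rpr_type: str | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise StructureValidationError(f"{self.molecule_id}: empty sequence")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureValidationError(
                    f"{self.molecule_id}: pair ({i},{j}) out of range for length {n}"
                )
            for k in (i, j):
                if k in seen:
                    raise StructureValidationError(
                        f"{self.molecule_id}: base {k + 1} participates in more than one pair"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired(self) -> dict[int, int]:
        """Symmetric index -> partner map."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


@dataclass
class Substructure:
    """A typed structural element with its length metric.

    ``length`` is base pairs for stems and nucleotides otherwise; absent
    substructures are represented by ``length == 0`` with an empty span, not
    by omission.  ``span`` lists 0-based closed intervals.
    """

    label: str
    kind: str
    length: int
    span: list[tuple[int, int]] = field(default_factory=list)
    gu_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown substructure kind {self.kind!r}")
        if self.length < 0:
            raise ValueError("substructure length must be non-negative")
        if self.kind not in STEM_KINDS and self.gu_count != 0:
            raise ValueError("gu_count is defined for stems only")
        if self.kind in STEM_KINDS and self.gu_count > self.length:
            raise ValueError("gu_count cannot exceed stem length")

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.span)


@dataclass(frozen=True)
class HomologyScheme:
    """Canonical universe of substructure labels with kind and domain maps.

    ``domain_map`` follows the RNase P convention: the specificity (S) domain
    is stem P7 and stems distal to it (P8-P12 side), the rest is the
    catalytic (C) domain.
    """

    universe: tuple[str, ...]
    kind_map: dict[str, str]
    domain_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("scheme labels must be unique")
        for lab in self.universe:
            kind = self.kind_map.get(lab)
            if kind is None:
                raise ValueError(f"label {lab!r} has no kind")
            if kind not in ALL_KINDS:
                raise ValueError(f"label {lab!r} has unknown kind {kind!r}")
            dom = self.domain_map.get(lab, "none")
            if dom not in {"S", "C", "none"}:
                raise ValueError(f"label {lab!r} has unknown domain {dom!r}")

    def domain(self, label: str) -> str:
        return self.domain_map.get(label, "none")

    def kind(self, label: str) -> str:
        return self.kind_map[label]


# ---------------------------------------------------------------------------
# parsing


def _parse_dotbracket_pairs(db: str, line_no: int = 1) -> set[tuple[int, int]]:
    stacks: dict[int, list[int]] = {k: [] for k in range(len(_OPENERS))}
    pairs: set[tuple[int, int]] = set()
    for col, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_OPENERS.index(ch)].append(col)
        elif ch in _CLOSERS:
            layer = _CLOSERS.index(ch)
            if not stacks[layer]:
                raise StructureParseError(
                    f"line {line_no}, column {col + 1}: unmatched {ch!r}"
                )
            i = stacks[layer].pop()
            pairs.add((i, col))
        else:
            raise StructureParseError(
                f"line {line_no}, column {col + 1}: illegal character {ch!r}"
            )
    for layer, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"line {line_no}, column {stack[-1] + 1}: unmatched {_OPENERS[layer]!r}"
            )
    return pairs


def _parse_dotbracket(text: str) -> SecondaryStructure:
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError("line 1: empty dot-bracket record")
    mol_id = "molecule"
    if lines[0].startswith(">"):
        mol_id = lines[0][1:].strip().split()[0] or "molecule"
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureParseError("line 1: expected sequence and structure lines")
    seq, db = lines[0].upper().replace("T", "U"), lines[1]
    if len(seq) != len(db):
        raise StructureParseError(
            f"line 2: structure length {len(db)} != sequence length {len(seq)}"
        )
    pairs = _parse_dotbracket_pairs(db, line_no=2)
    return SecondaryStructure(mol_id, seq, frozenset(pairs))


def _parse_columns(text: str, fmt: str) -> SecondaryStructure:
    """Shared reader for CT and bpseq (1-based on disk)."""
    seq: list[str] = []
    partner: list[int] = []
    mol_id = "molecule"
    body_started = False
    for ln_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fmt == "ct" and not body_started:
            # CT header: "<n> <title...>"
            try:
                int(fields[0])
            except ValueError as exc:
                raise StructureParseError(f"line {ln_no}: bad CT header") from exc
            if len(fields) > 1:
                mol_id = fields[1]
            body_started = True
            continue
        try:
            idx = int(fields[0])
            if fmt == "ct":
                base, pair_1b = fields[1], int(fields[4])
            else:  # bpseq: index base partner
                base, pair_1b = fields[1], int(fields[2])
        except (IndexError, ValueError) as exc:
            raise StructureParseError(f"line {ln_no}: malformed {fmt} row") from exc
        if idx != len(seq) + 1:
            raise StructureParseError(
                f"line {ln_no}: expected index {len(seq) + 1}, found {idx}"
            )
        seq.append(base.upper().replace("T", "U"))
        partner.append(pair_1b)
    if not seq:
        raise StructureParseError(f"line 1: empty {fmt} record")
    pairs: set[tuple[int, int]] = set()
    for i, p in enumerate(partner):
        if p == 0:
            continue
        j = p - 1
        if not (0 <= j < len(seq)):
            raise StructureParseError(f"partner index {p} out of range")
        if partner[j] != i + 1:
            raise StructureValidationError(
                f"asymmetric pairing between bases {i + 1} and {p}"
            )
        if i < j:
            pairs.add((i, j))
    return SecondaryStructure(mol_id, "".join(seq), frozenset(pairs))


def parse_structure(text: str, format: str = "dotbracket") -> SecondaryStructure:
    """Parse one structure record in dot-bracket, CT or bpseq format.

    Dot-bracket may use up to four bracket layers ``()[]{}<>`` for
    pseudoknots.  Raises :class:`StructureParseError` on malformed input and
    :class:`StructureValidationError` on pairing conflicts.
    """
    if format == "dotbracket":
        return _parse_dotbracket(text)
    if format in ("ct", "bpseq"):
        return _parse_columns(text, format)
    raise ValueError(f"unknown structure format {format!r}")


def read_structures(text: str) -> list[SecondaryStructure]:
    """Read a multi-record dot-bracket file (records introduced by ``>``)."""
    records: list[str] = []
    current: list[str] = []
    for ln in text.splitlines():
        if ln.startswith(">"):
            if current:
                records.append("\n".join(current))
            current = [ln]
        elif ln.strip():
            current.append(ln)
    if current:
        records.append("\n".join(current))
    return [parse_structure(rec, "dotbracket") for rec in records]


def write_dotbracket(ss: SecondaryStructure) -> str:
    """Render a structure as a dot-bracket record, assigning pseudoknot layers.

    Pairs are assigned greedily to the first bracket layer on which they do
    not cross an already-placed pair, so a round trip through
    :func:`parse_structure` reproduces the pair set exactly (layer labels may
    differ from the original input).
    """
    n = len(ss.sequence)
    chars = ["."] * n
    layers: list[list[tuple[int, int]]] = [[] for _ in _OPENERS]
    for i, j in sorted(ss.pairs):
        for lv, placed in enumerate(layers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in placed):
                placed.append((i, j))
                chars[i] = _OPENERS[lv]
                chars[j] = _CLOSERS[lv]
                break
        else:  # pragma: no cover - >4 mutually crossing layers
            raise StructureValidationError(
                f"{ss.molecule_id}: more than {len(_OPENERS)} mutually crossing layers"
            )
    return f">{ss.molecule_id}\n{ss.sequence}\n{''.join(chars)}\n"


# ---------------------------------------------------------------------------
# decomposition


def _stems(ss: SecondaryStructure) -> list[list[tuple[int, int]]]:
    """Maximal runs of stacked pairs; a bulge of >=1 nt terminates a stem."""
    pairs = set(ss.pairs)
    stems = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # continuation of a run started outside-in
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pairs:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        stems.append(run)
    return stems


def _noncrossing_subset(stems: list[list[tuple[int, int]]]) -> list[bool]:
    """Greedily mark stems forming a non-crossing nesting skeleton.

    Stems are accepted in 5' order; a stem crossing an accepted one is a
    pseudoknot stem and is excluded from the nesting skeleton (it remains an
    ordinary stem for coding purposes).
    """

    def crosses(s1: list[tuple[int, int]], s2: list[tuple[int, int]]) -> bool:
        a, b = s1[0]
        c, d = s2[0]
        return (a < c < b < d) or (c < a < d < b)

    accepted: list[list[tuple[int, int]]] = []
    flags = []
    for s in stems:
        if any(crosses(s, t) for t in accepted):
            flags.append(False)
        else:
            accepted.append(s)
            flags.append(True)
    return flags


def decompose(ss: SecondaryStructure) -> list[Substructure]:
    """Decompose a structure into stems and loop-type substructures.

    Stems are maximal stacked runs of pairs.  Unpaired regions are classified
    from the nesting skeleton of non-crossing stems: a region immediately
    closed by a single pair is a hairpin; regions between two nested stems
    form an internal loop (both sides unpaired) or a bulge (one side empty);
    loops with three or more incident stems yield multiloop segments;
    unpaired termini are free ends and unpaired stretches between top-level
    stems are joints.  ``gu_count`` counts G:U and U:G pairs per stem.  The
    returned spans partition the molecule.
    """
    n = len(ss.sequence)
    stems = _stems(ss)
    out: list[Substructure] = []
    for k, run in enumerate(stems):
        gu = sum(
            1 for i, j in run if {ss.sequence[i], ss.sequence[j]} == {"G", "U"}
        )
        left = (run[0][0], run[-1][0])
        right = (run[-1][1], run[0][1])
        out.append(
            Substructure(
                label=f"stem{k + 1}",
                kind="stem",
                length=len(run),
                span=[left, right],
                gu_count=gu,
            )
        )

    # nesting skeleton: which stem (if any) most closely encloses each position
    nest_flags = _noncrossing_subset(stems)
    skeleton = [s for s, ok in zip(stems, nest_flags) if ok]
    paired = ss.paired

    # enclosing skeleton stem for every position (None = exterior)
    enclosing: list[int | None] = [None] * n
    order = sorted(range(len(skeleton)), key=lambda k: skeleton[k][0][1] - skeleton[k][0][0], reverse=True)
    for k in order:  # paint from outermost to innermost
        i, j = skeleton[k][-1]  # innermost pair of the stem
        for p in range(i + 1, j):
            enclosing[p] = k

    # maximal unpaired runs
    runs: list[tuple[int, int]] = []
    p = 0
    while p < n:
        if p in paired:
            p += 1
            continue
        q = p
        while q + 1 < n and (q + 1) not in paired:
            q += 1
        runs.append((p, q))
        p = q + 1

    # group unpaired runs by the loop they belong to (enclosing skeleton stem)
    loops: dict[int | None, list[tuple[int, int]]] = {}
    for a, b in runs:
        loops.setdefault(enclosing[a], []).append((a, b))

    # enclosing skeleton stem of a position, paired positions included;
    # used to find the stems (pseudoknots too) branching directly off a loop
    enclosing_all = enclosing

    def direct_children(k: int) -> list[int]:
        i, j = skeleton[k][-1]
        kids = []
        for s_idx, s in enumerate(stems):
            a, b = s[0][0], s[0][1]
            if i < a and b < j and enclosing_all[a] == k:
                kids.append(s_idx)
        return kids

    hp = bu = il = ml = jt = 0
    for k_loop, regions in sorted(
        loops.items(), key=lambda kv: (kv[0] is not None, kv[1][0][0])
    ):
        regions = sorted(regions)
        if k_loop is None:
            for a, b in regions:
                if a == 0 or b == n - 1:
                    out.append(
                        Substructure(
                            label="free5" if a == 0 else "free3",
                            kind="free_end",
                            length=b - a + 1,
                            span=[(a, b)],
                        )
                    )
                else:
                    jt += 1
                    out.append(
                        Substructure(
                            label=f"joint{jt}",
                            kind="joint",
                            length=b - a + 1,
                            span=[(a, b)],
                        )
                    )
            continue
        kids = direct_children(k_loop)
        n_branch = 1 + len(kids)  # closing stem + children (incl. pseudoknots)
        if n_branch == 1:
            hp += 1
            for a, b in regions:
                out.append(
                    Substructure(
                        label=f"hairpin{hp}",
                        kind="hairpin",
                        length=b - a + 1,
                        span=[(a, b)],
                    )
                )
        elif n_branch == 2 and len(regions) <= 2:
            total = sum(b - a + 1 for a, b in regions)
            if len(regions) == 1:
                bu += 1
                out.append(
                    Substructure(
                        label=f"bulge{bu}", kind="bulge", length=total, span=regions
                    )
                )
            else:
                il += 1
                out.append(
                    Substructure(
                        label=f"internal{il}",
                        kind="internal_loop",
                        length=total,
                        span=regions,
                    )
                )
        else:
            for a, b in regions:
                ml += 1
                out.append(
                    Substructure(
                        label=f"multiloop{ml}",
                        kind="multiloop_segment",
                        length=b - a + 1,
                        span=[(a, b)],
                    )
                )

    out.sort(key=lambda s: s.span[0][0] if s.span else n)
    return out


# ---------------------------------------------------------------------------
# homology labeling


def read_annotation(text: str) -> dict[str, list[tuple[int, int, str]]]:
    """Read a tab-separated annotation file: molecule_id, start, end, label.

    Coordinates are 1-based inclusive on disk and converted to 0-based closed
    intervals.
    """
    out: dict[str, list[tuple[int, int, str]]] = {}
    for ln_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise StructureParseError(f"line {ln_no}: expected 4 tab-separated fields")
        mol, start, end, label = fields
        try:
            a, b = int(start) - 1, int(end) - 1
        except ValueError as exc:
            raise StructureParseError(f"line {ln_no}: bad coordinates") from exc
        if a < 0 or b < a:
            raise StructureParseError(f"line {ln_no}: bad interval {start}-{end}")
        out.setdefault(mol, []).append((a, b, label))
    return out


def _covered(span: list[tuple[int, int]], intervals: list[tuple[int, int]]) -> bool:
    for a, b in span:
        for p in range(a, b + 1):
            if not any(x <= p <= y for x, y in intervals):
                return False
    return True


def label_substructures(
    subs: list[Substructure],
    scheme: HomologyScheme,
    annotation: list[tuple[int, int, str]],
) -> list[Substructure]:
    """Attach canonical labels to decomposed substructures.

    Each substructure receives the scheme label whose annotated intervals
    cover its whole span.  Several same-kind substructures may share one
    label: stems merge into a composite coaxial tract (lengths in base pairs
    add; internal loops of the tract that carry no annotation of their own
    are absorbed into the composite span), loops merge by summing
    nucleotides.  Universe labels with no match are emitted with length 0.
    A label whose scheme kind conflicts with the decomposed kind raises
    :class:`LabelingError`.
    """
    by_label: dict[str, list[tuple[int, int]]] = {}
    for a, b, lab in annotation:
        if lab not in scheme.universe:
            raise LabelingError(f"annotation label {lab!r} not in scheme universe")
        by_label.setdefault(lab, []).append((a, b))

    assigned: dict[str, list[Substructure]] = {lab: [] for lab in scheme.universe}
    unlabeled: list[Substructure] = []
    for sub in subs:
        if not sub.span:
            continue
        matches = [lab for lab, ivs in by_label.items() if _covered(sub.span, ivs)]
        if not matches:
            unlabeled.append(sub)
            continue
        # prefer a label of matching kind class; among those, smallest cover
        same_kind = [
            lab
            for lab in matches
            if (scheme.kind(lab) in STEM_KINDS) == (sub.kind in STEM_KINDS)
        ]
        pool = same_kind or matches
        lab = min(pool, key=lambda L: sum(y - x for x, y in by_label[L]))
        assigned[lab].append(sub)

    out: list[Substructure] = []
    for lab in scheme.universe:
        kind = scheme.kind(lab)
        members = assigned[lab]
        stems = [s for s in members if s.kind in STEM_KINDS]
        loops = [s for s in members if s.kind not in STEM_KINDS]
        if kind in STEM_KINDS:
            if loops and not stems:
                raise LabelingError(
                    f"label {lab!r} is a stem label but matched only "
                    f"{loops[0].kind!r} substructures"
                )
            extra = [
                l
                for l in loops
                if not _absorbable(l, stems)
            ]
            if extra:
                raise LabelingError(
                    f"label {lab!r} (stem) cannot absorb {extra[0].kind!r} at "
                    f"{extra[0].span}"
                )
            length = sum(s.length for s in stems)
            gu = sum(s.gu_count for s in stems)
            span = sorted(iv for s in stems + loops for iv in s.span)
            out.append(Substructure(lab, "stem", length, span, gu))
        else:
            if stems:
                raise LabelingError(
                    f"label {lab!r} is a {kind} label but matched a stem"
                )
            if loops and any(l.kind in STEM_KINDS for l in loops):  # pragma: no cover
                raise LabelingError(f"label {lab!r}: kind mismatch")
            length = sum(l.length for l in loops)
            span = sorted(iv for l in loops for iv in l.span)
            out.append(Substructure(lab, kind, length, span, 0))

    if unlabeled:
        s = unlabeled[0]
        raise LabelingError(
            f"substructure {s.kind} at {s.span} is not covered by any annotation"
        )
    return out


def _absorbable(loop: Substructure, stems: list[Substructure]) -> bool:
    """A loop absorbs into a coaxial stem tract iff it lies strictly between
    two stem segments of the tract (bulges/internal loops inside the tract)."""
    if loop.kind not in {"bulge", "internal_loop"}:
        return False
    lo = min(a for a, _ in loop.span)
    hi = max(b for _, b in loop.span)
    before = any(any(b < lo for _, b in s.span) for s in stems)
    after = any(any(a > hi for a, _ in s.span) for s in stems)
    return before and after
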