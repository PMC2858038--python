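"""Polarized ordered multistate character matrices.

Labeled substructures become columns of a taxa x characters matrix whose
states are the substructure lengths written in an alphanumeric alphabet
(``0``-``9``, ``A``-``Z``, ``a``-``z`` for 0..61).  Characters come in two
classes: *stabilizing* (stem lengths in base pairs, G:U pair counts) whose
hypothetical-ancestor state is the column maximum, and *de-stabilizing*
(loop and unpaired-segment lengths in nucleotides) whose ancestral state is
0.  The ancestor row roots parsimony trees intrinsically; matrices can be
transposed to build trees of substructures instead of trees of molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .structure import HomologyScheme, Substructure, STEM_KINDS

__all__ = [
    "STATE_ALPHABET",
    "MISSING",
    "CharacterDef",
    "CharacterMatrix",
    "SequenceBlock",
    "StateOverflowWarning",
    "encode_state",
    "decode_state",
    "build_matrix",
    "add_ancestor",
    "transpose",
    "partition",
    "combine_total_evidence",
]

STATE_ALPHABET = (
    "0123456789"
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
)
MAX_STATE = len(STATE_ALPHABET) - 1  # 61
MISSING = -1  # internal code for '?'

ANCESTOR_NAME = "ANC"

_NUC_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "-": MISSING, "?": MISSING}
_NUC_SYM = "ACGU"


class StateOverflowWarning(UserWarning):
    """A length exceeded the closed 62-symbol alphabet and was clamped."""


def encode_state(value: int) -> str:
    """Encode a non-negative length as an alphanumeric state symbol.

    Values above 61 clamp to ``'z'`` with a :class:`StateOverflowWarning`.
    """
    if value < 0:
        raise ValueError(f"negative character state {value}")
    if value > MAX_STATE:
        warnings.warn(
            f"state {value} exceeds alphabet maximum {MAX_STATE}; clamped to 'z'",
            StateOverflowWarning,
            stacklevel=2,
        )
        return STATE_ALPHABET[-1]
    return STATE_ALPHABET[value]


def decode_state(symbol: str) -> int:
    """Decode a state symbol; ``?`` decodes to the missing code."""
    if symbol == "?":
        return MISSING
    idx = STATE_ALPHABET.find(symbol)
    if idx < 0:
        raise ValueError(f"unknown state symbol {symbol!r}")
    return idx


@dataclass(frozen=True)
class CharacterDef:
    """One column: a substructure metric with its polarity class."""

    char_id: str
    kind: str  # stabilizing | destabilizing | sequence
    domain: str = "none"  # S | C | none
    metric: str = "stem_bp"  # stem_bp | gu_pairs | loop_nt | unpaired_nt | nucleotide
    ordered: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"stabilizing", "destabilizing", "sequence"}:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.metric in {"stem_bp", "gu_pairs"} and self.kind != "stabilizing":
            raise ValueError(f"{self.char_id}: {self.metric} characters are stabilizing")
        if self.metric in {"loop_nt", "unpaired_nt"} and self.kind != "destabilizing":
            raise ValueError(
                f"{self.char_id}: {self.metric} characters are de-stabilizing"
            )

    @property
    def label_root(self) -> str:
        return self.char_id.split(".")[0]


@dataclass
class CharacterMatrix:
    """Taxa x ordered multistate characters, with an optional ancestor row.

    ``values`` holds integer states (missing = -1).  ``orientation`` records
    whether rows are molecules or substructures; ``taxon_meta`` carries
    optional per-taxon ``superkingdom`` / ``rpr_type`` tags used by
    superkingdom partitions.
    """

    taxa: list[str]
    chars: list[CharacterDef]
    values: np.ndarray
    ancestor: np.ndarray | None = None
    orientation: str = "molecules_as_taxa"
    taxon_meta: dict[str, dict[str, str]] = field(default_factory=dict)
    _source_chars: list[CharacterDef] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != (len(self.taxa), len(self.chars)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.chars)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.values.size and self.values.max() > MAX_STATE:
            raise ValueError("state exceeds alphabet maximum; encode first")
        if self.ancestor is not None:
            self.ancestor = np.asarray(self.ancestor, dtype=np.int16)
            if self.ancestor.shape != (len(self.chars),):
                raise ValueError("ancestor row length does not match characters")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.chars)

    def char_ids(self) -> list[str]:
        return [c.char_id for c in self.chars]

    def symbol_rows(self) -> list[str]:
        return ["".join(_sym(v) for v in row) for row in self.values]

    def ancestor_symbols(self) -> str | None:
        if self.ancestor is None:
            return None
        return "".join(_sym(v) for v in self.ancestor)

    def row(self, taxon: str) -> np.ndarray:
        return self.values[self.taxa.index(taxon)]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.taxa),
            list(self.chars),
            self.values.copy(),
            None if self.ancestor is None else self.ancestor.copy(),
            self.orientation,
            {t: dict(m) for t, m in self.taxon_meta.items()},
            self._source_chars,
        )

    # ------------------------------------------------------------------ TSV
    def to_tsv(self) -> str:
        buf = StringIO()
        buf.write("taxon\t" + "\t".join(self.char_ids()) + "\n")
        buf.write("#kind\t" + "\t".join(c.kind for c in self.chars) + "\n")
        buf.write("#domain\t" + "\t".join(c.domain for c in self.chars) + "\n")
        buf.write("#metric\t" + "\t".join(c.metric for c in self.chars) + "\n")
        if self.ancestor is not None:
            buf.write(
                f"#ancestor\t" + "\t".join(_sym(v) for v in self.ancestor) + "\n"
            )
        for taxon, row in zip(self.taxa, self.values):
            cells = [_sym(v) for v in row]
            meta = self.taxon_meta.get(taxon, {})
            buf.write(taxon + "\t" + "\t".join(cells))
            if meta:
                buf.write(
                    "\t#" + meta.get("superkingdom", "") + "/" + meta.get("rpr_type", "")
                )
            buf.write("\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "CharacterMatrix":
        lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[0] != "taxon":
            raise ValueError("TSV matrix must start with a 'taxon' header column")
        ids = header[1:]
        kinds = domains = metrics = None
        ancestor = None
        taxa: list[str] = []
        rows: list[list[int]] = []
        meta: dict[str, dict[str, str]] = {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            key = fields[0]
            if key == "#kind":
                kinds = fields[1:]
            elif key == "#domain":
                domains = fields[1:]
            elif key == "#metric":
                metrics = fields[1:]
            elif key == "#ancestor":
                ancestor = np.array([decode_state(s) for s in fields[1:]], np.int16)
            else:
                cells = fields[1 : 1 + len(ids)]
                if len(cells) != len(ids):
                    raise ValueError(f"row {key!r}: expected {len(ids)} states")
                taxa.append(key)
                rows.append([decode_state(s) for s in cells])
                if len(fields) > 1 + len(ids) and fields[1 + len(ids)].startswith("#"):
                    sk, _, rt = fields[1 + len(ids)][1:].partition("/")
                    m = {}
                    if sk:
                        m["superkingdom"] = sk
                    if rt:
                        m["rpr_type"] = rt
                    if m:
                        meta[key] = m
        if kinds is None:
            kinds = ["stabilizing"] * len(ids)
        if domains is None:
            domains = ["none"] * len(ids)
        if metrics is None:
            metrics = [
                "stem_bp" if k == "stabilizing" else "loop_nt" for k in kinds
            ]
        chars = [
            CharacterDef(i, k, d, m, ordered=(k != "sequence"))
            for i, k, d, m in zip(ids, kinds, domains, metrics)
        ]
        return cls(taxa, chars, np.array(rows, np.int16), ancestor, taxon_meta=meta)


def _sym(v: int) -> str:
    return "?" if v == MISSING else STATE_ALPHABET[int(v)]


@dataclass
class SequenceBlock:
    """Aligned nucleotide columns (unordered characters) for total evidence."""

    taxa: list[str]
    rows: list[str]  # aligned sequences over A,C,G,U,-,?

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one aligned row per taxon required")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, text: str) -> "SequenceBlock":
        taxa, rows, cur = [], [], []
        for ln in text.splitlines():
            if ln.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                taxa.append(ln[1:].strip().split()[0])
            elif ln.strip():
                cur.append(ln.strip().upper().replace("T", "U"))
        if cur:
            rows.append("".join(cur))
        return cls(taxa, rows)


# ---------------------------------------------------------------------------
# construction


_KIND_FOR_SUB = {
    "stem": "stabilizing",
    "hairpin": "destabilizing",
    "bulge": "destabilizing",
    "internal_loop": "destabilizing",
    "multiloop_segment": "destabilizing",
    "free_end": "destabilizing",
    "joint": "destabilizing",
}

_METRIC_FOR_SUB = {
    "stem": "stem_bp",
    "hairpin": "loop_nt",
    "bulge": "loop_nt",
    "internal_loop": "loop_nt",
    "multiloop_segment": "unpaired_nt",
    "free_end": "unpaired_nt",
    "joint": "unpaired_nt",
}


def characters_for_scheme(
    scheme: HomologyScheme, include_gu: bool = False
) -> list[CharacterDef]:
    """One ``<label>.len`` column per scheme label (plus ``<label>.gu`` for
    stems when G:U counts are scored)."""
    chars: list[CharacterDef] = []
    for lab in scheme.universe:
        kind = scheme.kind(lab)
        dom = scheme.domain(lab)
        if kind in STEM_KINDS:
            chars.append(CharacterDef(f"{lab}.len", "stabilizing", dom, "stem_bp"))
            if include_gu:
                chars.append(CharacterDef(f"{lab}.gu", "stabilizing", dom, "gu_pairs"))
        else:
            metric = _METRIC_FOR_SUB[kind]
            chars.append(CharacterDef(f"{lab}.len", "destabilizing", dom, metric))
    return chars


def build_matrix(
    molecules: list[tuple[str, list[Substructure]]],
    scheme: HomologyScheme,
    include_gu: bool = False,
    taxon_meta: dict[str, dict[str, str]] | None = None,
) -> CharacterMatrix:
    """Assemble the molecules x characters matrix from labeled substructures.

    Missing substructures (length 0) code as state 0.  Lengths above the
    61-state alphabet clamp with a warning.
    """
    if not molecules:
        raise ValueError("empty molecule set")
    chars = characters_for_scheme(scheme, include_gu)
    col_index = {c.char_id: k for k, c in enumerate(chars)}
    taxa: list[str] = []
    rows = np.zeros((len(molecules), len(chars)), dtype=np.int16)
    for r, (mol_id, subs) in enumerate(molecules):
        if mol_id in taxa:
            raise ValueError(f"duplicate taxon id {mol_id!r}")
        taxa.append(mol_id)
        for sub in subs:
            key = f"{sub.label}.len"
            if key not in col_index:
                raise ValueError(f"substructure label {sub.label!r} not in scheme")
            rows[r, col_index[key]] = decode_state(encode_state(sub.length))
            gu_key = f"{sub.label}.gu"
            if gu_key in col_index:
                rows[r, col_index[gu_key]] = decode_state(encode_state(sub.gu_count))
    return CharacterMatrix(
        taxa, chars, rows, taxon_meta=dict(taxon_meta or {}),
        orientation="molecules_as_taxa",
    )


# ---------------------------------------------------------------------------
# polarization / reshaping


def add_ancestor(M: CharacterMatrix, polarity: str = "standard") -> CharacterMatrix:
    """Attach the hypothetical-ancestor row.

    Standard polarity: stabilizing characters take the column maximum
    (structures erode from a maximal ancestral state), de-stabilizing
    characters take 0 (unpaired regions grow from nothing).  ``reversed``
    flips the rule, which is useful to test the polarization model itself.
    Sequence columns are left missing in the ancestor.
    """
    if M.n_taxa < 1:
        raise ValueError("cannot polarize an empty matrix")
    if polarity not in {"standard", "reversed"}:
        raise ValueError(f"unknown polarity {polarity!r}")
    anc = np.zeros(M.n_chars, dtype=np.int16)
    col_max = M.values.max(axis=0) if M.n_taxa else np.zeros(M.n_chars, np.int16)
    col_min = M.values.min(axis=0) if M.n_taxa else np.zeros(M.n_chars, np.int16)
    for k, c in enumerate(M.chars):
        if c.kind == "sequence":
            anc[k] = MISSING
        elif c.kind == "stabilizing":
            anc[k] = col_max[k] if polarity == "standard" else col_min[k]
        else:
            anc[k] = 0 if polarity == "standard" else col_max[k]
    out = M.copy()
    out.ancestor = anc
    return out


def transpose(M: CharacterMatrix) -> CharacterMatrix:
    """Swap taxa and characters to build trees of substructures.

    Only single-kind matrices can be transposed (the evolutionary model of a
    stem differs from that of a loop, so substructure taxa of mixed kind are
    not comparable); partition first.  The ancestor row is dropped and must
    be re-derived on the transposed matrix.
    """
    kinds = {c.kind for c in M.chars}
    if len(kinds) > 1:
        raise ValueError(
            f"cannot transpose a mixed-kind matrix (kinds {sorted(kinds)}); "
            "partition by character kind first"
        )
    kind = kinds.pop() if kinds else "stabilizing"
    if M._source_chars is not None and len(M._source_chars) == M.n_taxa and all(
        c.char_id == t for c, t in zip(M._source_chars, M.taxa)
    ):
        new_chars = list(M._source_chars)
    else:
        metric = M.chars[0].metric if M.chars else "stem_bp"
        new_chars = [
            CharacterDef(t, kind, "none", metric, ordered=True) for t in M.taxa
        ]
    new_orientation = (
        "substructures_as_taxa"
        if M.orientation == "molecules_as_taxa"
        else "molecules_as_taxa"
    )
    return CharacterMatrix(
        taxa=M.char_ids(),
        chars=new_chars,
        values=M.values.T.copy(),
        ancestor=None,
        orientation=new_orientation,
        taxon_meta={},
        _source_chars=list(M.chars),
    )


def _expand_label_root(root: str) -> set[str]:
    """Expand composite coaxial labels: P10-11 covers {P10, P11}."""
    if "-" not in root or not root.startswith("P"):
        return {root}
    left, _, right = root.partition("-")
    right = right.lstrip("P")
    try:
        lo = int(left[1:].split(".")[0])
        hi = int(right.split(".")[0])
    except ValueError:
        return {root}
    return {f"P{k}" for k in range(lo, hi + 1)} | {root}


_CORE_A = ["P1", "P2", "P3", "P4", "P10", "P11"]
_CORE_B = ["P1", "P2", "P3", "P4", "P7", "P9", "P10", "P11"]


def partition(M: CharacterMatrix, scheme: str) -> CharacterMatrix:
    """Extract a named submatrix.

    ``domain_S`` / ``domain_C`` keep characters of one folding domain,
    ``stabilizing`` / ``destabilizing`` keep one character class,
    ``superkingdom:<name>`` keeps taxa of one superkingdom, and ``core_A`` /
    ``core_B`` keep the conserved helical cores (P1-P4 plus P10/P11, or
    P1-P4, P7 and P9-P11).  Empty results raise.
    """
    if scheme.startswith("superkingdom:"):
        name = scheme.split(":", 1)[1]
        keep = [
            t
            for t in M.taxa
            if M.taxon_meta.get(t, {}).get("superkingdom") == name
        ]
        if not keep:
            raise ValueError(f"no taxa in superkingdom {name!r}")
        idx = [M.taxa.index(t) for t in keep]
        out = CharacterMatrix(
            keep,
            list(M.chars),
            M.values[idx],
            None,
            M.orientation,
            {t: dict(M.taxon_meta.get(t, {})) for t in keep},
        )
        if M.ancestor is not None:
            out = add_ancestor(out)
        return out

    if scheme in {"domain_S", "domain_C"}:
        dom = scheme[-1]
        cols = [k for k, c in enumerate(M.chars) if c.domain == dom]
    elif scheme in {"stabilizing", "destabilizing"}:
        cols = [k for k, c in enumerate(M.chars) if c.kind == scheme]
    elif scheme in {"core_A", "core_B"}:
        required = _CORE_A if scheme == "core_A" else _CORE_B
        covered: set[str] = set()
        cols = []
        for k, c in enumerate(M.chars):
            expand = _expand_label_root(c.label_root)
            if expand & set(required):
                cols.append(k)
                covered |= expand
        missing = [r for r in required if r not in covered]
        if missing:
            raise ValueError(f"{scheme}: scheme lacks required stems {missing}")
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")
    if not cols:
        raise ValueError(f"partition {scheme!r} selects no characters")
    out = CharacterMatrix(
        list(M.taxa),
        [M.chars[k] for k in cols],
        M.values[:, cols],
        None if M.ancestor is None else M.ancestor[cols],
        M.orientation,
        {t: dict(m) for t, m in M.taxon_meta.items()},
    )
    return out


def combine_total_evidence(M: CharacterMatrix, S: SequenceBlock) -> CharacterMatrix:
    """Concatenate structural characters with aligned sequence columns.

    Sequence columns are unordered; gaps are treated as missing and the
    ancestor state of every sequence column is missing, so sequence data
    contribute grouping signal but not rooting polarity.
    """
    if S.n_columns == 0:
        return M.copy()
    if set(S.taxa) != set(M.taxa):
        raise ValueError("sequence block and matrix must share the same taxa")
    order = [S.taxa.index(t) for t in M.taxa]
    seq_vals = np.full((M.n_taxa, S.n_columns), MISSING, np.int16)
    for r, si in enumerate(order):
        for k, ch in enumerate(S.rows[si]):
            code = _NUC_CODE.get(ch.upper())
            if code is None:
                raise ValueError(f"illegal alignment symbol {ch!r}")
            seq_vals[r, k] = code
    seq_chars = [
        CharacterDef(f"seq{k + 1}", "sequence", "none", "nucleotide", ordered=False)
        for k in range(S.n_columns)
    ]
    values = np.hstack([M.values, seq_vals])
    ancestor = None
    if M.ancestor is not None:
        ancestor = np.concatenate(
            [M.ancestor, np.full(S.n_columns, MISSING, np.int16)]
        )
    return CharacterMatrix(
        list(M.taxa),
        list(M.chars) + seq_chars,
        values,
        ancestor,
        M.orientation,
        {t: dict(m) for t, m in M.taxon_meta.items()},
    )
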