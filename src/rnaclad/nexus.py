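"""NEXUS interchange for polarized character matrices.

The writer emits the three blocks a PAUP* run needs: a DATA block with the
alphanumeric matrix, an ASSUMPTIONS block declaring structural characters as
linearly ordered (sequence columns unordered), and a PAUP block carrying the
hypothetical-ancestor states on an ``ANCSTATES`` line.  Character kind,
domain and metric ride along in bracketed NEXUS comments (ignored by other
programs) so that ``read_nexus(write_nexus(M))`` reproduces the matrix.
"""

from __future__ import annotations

import re

import numpy as np

from .matrix import (
    MISSING,
    CharacterDef,
    CharacterMatrix,
    decode_state,
    _NUC_SYM,
)

__all__ = ["write_nexus", "read_nexus", "NexusError"]


class NexusError(ValueError):
    """Malformed NEXUS block structure."""


_KIND_CODE = {"stabilizing": "s", "destabilizing": "d", "sequence": "q"}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}
_METRIC_CODE = {
    "stem_bp": "b",
    "gu_pairs": "g",
    "loop_nt": "l",
    "unpaired_nt": "u",
    "nucleotide": "n",
}
_CODE_METRIC = {v: k for k, v in _METRIC_CODE.items()}
_DOMAIN_CODE = {"S": "S", "C": "C", "none": "N"}
_CODE_DOMAIN = {v: k for k, v in _DOMAIN_CODE.items()}


def _quote(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _sym_cell(c: CharacterDef, v: int) -> str:
    if v == MISSING:
        return "?"
    if c.metric == "nucleotide":
        return _NUC_SYM[v]
    from .matrix import STATE_ALPHABET

    return STATE_ALPHABET[v]


def _ranges(indices: list[int]) -> str:
    """1-based NEXUS range list, e.g. [0,1,2,5] -> '1-3 6'."""
    if not indices:
        return ""
    parts = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
            continue
        parts.append(f"{start + 1}-{prev + 1}" if prev > start else f"{start + 1}")
        start = prev = i
    parts.append(f"{start + 1}-{prev + 1}" if prev > start else f"{start + 1}")
    return " ".join(parts)


def write_nexus(M: CharacterMatrix, ancstates_name: str = "polarized") -> str:
    """Serialize a matrix as DATA + ASSUMPTIONS + PAUP NEXUS blocks."""
    pad = max((len(_quote(t)) for t in M.taxa), default=8) + 2
    lines = ["#NEXUS", ""]
    lines.append("BEGIN DATA;")
    lines.append(f"    DIMENSIONS NTAX={M.n_taxa} NCHAR={M.n_chars};")
    from .matrix import STATE_ALPHABET

    # declare only the symbol prefix in use: other NEXUS consumers with
    # case-insensitive state alphabets can then read small-state matrices
    non_seq = [k for k, c in enumerate(M.chars) if c.metric != "nucleotide"]
    max_used = 0
    if non_seq:
        max_used = int(M.values[:, non_seq].max(initial=0))
        if M.ancestor is not None:
            max_used = max(max_used, int(M.ancestor[non_seq].max(initial=0)))
    symbols = STATE_ALPHABET[: max(10, max_used + 1)]
    lines.append(
        f'    FORMAT SYMBOLS="{symbols}" MISSING=? GAP=- INTERLEAVE=NO;'
    )
    lines.append(
        "    CHARLABELS " + " ".join(_quote(c.char_id) for c in M.chars) + ";"
    )
    meta = "".join(_KIND_CODE[c.kind] for c in M.chars)
    doms = "".join(_DOMAIN_CODE[c.domain] for c in M.chars)
    mets = "".join(_METRIC_CODE[c.metric] for c in M.chars)
    lines.append(f"    [&kinds={meta}]")
    lines.append(f"    [&domains={doms}]")
    lines.append(f"    [&metrics={mets}]")
    lines.append("    MATRIX")
    for taxon, row in zip(M.taxa, M.values):
        cells = "".join(_sym_cell(c, v) for c, v in zip(M.chars, row))
        lines.append(f"        {_quote(taxon):<{pad}}{cells}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    ordered = [k for k, c in enumerate(M.chars) if c.ordered]
    unordered = [k for k, c in enumerate(M.chars) if not c.ordered]
    lines.append("BEGIN ASSUMPTIONS;")
    typeset = []
    if ordered:
        typeset.append(f"ord: {_ranges(ordered)}")
    if unordered:
        typeset.append(f"unord: {_ranges(unordered)}")
    lines.append("    TYPESET * default = " + ", ".join(typeset) + ";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN PAUP;")
    if M.ancestor is not None:
        anc = "".join(_sym_cell(c, v) for c, v in zip(M.chars, M.ancestor))
        lines.append(f"    ANCSTATES {ancstates_name} VECTOR = {anc};")
        lines.append(f"    SET ANCSTATES={ancstates_name};")
    lines.append("END;")
    lines.append("")
    return "\n".join(lines)


def _strip_comments(text: str, keep: dict[str, str]) -> str:
    """Remove [...] comments, harvesting the [&key=value] metadata ones."""

    def repl(m: re.Match) -> str:
        body = m.group(1)
        mm = re.fullmatch(r"&(\w+)=(\S+)", body.strip())
        if mm:
            keep[mm.group(1)] = mm.group(2)
        return " "

    return re.sub(r"\[([^\]]*)\]", repl, text)


def _tokens(text: str) -> list[str]:
    out = []
    for m in re.finditer(r"'((?:[^']|'')*)'|(\S+)", text):
        if m.group(1) is not None:
            out.append(m.group(1).replace("''", "'"))
        else:
            out.append(m.group(2))
    return out


def read_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS file written by :func:`write_nexus`.

    Recovers taxa, states, character labels, ordered/unordered typing and
    the ancestor row; character kind/domain/metric come from the bracketed
    metadata comments when present, else are inferred from the typeset
    (ordered columns default to stabilizing stems, unordered to sequence).
    """
    meta: dict[str, str] = {}
    text = _strip_comments(text, meta)
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise NexusError("missing #NEXUS header")

    blocks = dict(
        re.findall(
            r"BEGIN\s+(\w+)\s*;(.*?)END\s*;", text, re.IGNORECASE | re.DOTALL
        )
    )
    blocks = {k.upper(): v for k, v in blocks.items()}
    if "DATA" not in blocks:
        raise NexusError("no DATA block")
    data = blocks["DATA"]

    m = re.search(
        r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)\s*;", data, re.IGNORECASE
    )
    if not m:
        raise NexusError("DATA block lacks DIMENSIONS")
    ntax, nchar = int(m.group(1)), int(m.group(2))

    labels: list[str] | None = None
    m = re.search(r"CHARLABELS\s+(.*?);", data, re.IGNORECASE | re.DOTALL)
    if m:
        labels = _tokens(m.group(1))
        if len(labels) != nchar:
            raise NexusError(f"expected {nchar} CHARLABELS, found {len(labels)}")

    m = re.search(r"MATRIX\s+(.*?);", data, re.IGNORECASE | re.DOTALL)
    if not m:
        raise NexusError("DATA block lacks MATRIX")
    rows = _tokens(m.group(1))
    if len(rows) != 2 * ntax:
        raise NexusError(
            f"MATRIX should hold {ntax} taxon/states pairs, found {len(rows)} tokens"
        )
    taxa = rows[0::2]
    cells = rows[1::2]

    ordered_mask = [True] * nchar
    assumptions = blocks.get("ASSUMPTIONS", "")
    mt = re.search(r"TYPESET[^=]*=\s*(.*?);", assumptions, re.IGNORECASE | re.DOTALL)
    if mt:
        for part in mt.group(1).split(","):
            name, _, rng = part.partition(":")
            is_ord = name.strip().lower().startswith("ord")
            for tok in rng.split():
                if "-" in tok:
                    a, b = tok.split("-")
                    idxs = range(int(a) - 1, int(b))
                else:
                    idxs = [int(tok) - 1]
                for i in idxs:
                    ordered_mask[i] = is_ord

    kinds_code = meta.get("kinds", "")
    doms_code = meta.get("domains", "")
    mets_code = meta.get("metrics", "")
    chars: list[CharacterDef] = []
    for k in range(nchar):
        if k < len(kinds_code):
            kind = _CODE_KIND[kinds_code[k]]
            metric = _CODE_METRIC[mets_code[k]] if k < len(mets_code) else "stem_bp"
            dom = _CODE_DOMAIN[doms_code[k]] if k < len(doms_code) else "none"
        elif ordered_mask[k]:
            kind, metric, dom = "stabilizing", "stem_bp", "none"
        else:
            kind, metric, dom = "sequence", "nucleotide", "none"
        cid = labels[k] if labels else f"char{k + 1}"
        chars.append(CharacterDef(cid, kind, dom, metric, ordered=ordered_mask[k]))

    def decode_cell(c: CharacterDef, s: str) -> int:
        if s in "?-":
            return MISSING
        if c.metric == "nucleotide":
            code = _NUC_SYM.find(s.upper().replace("T", "U"))
            if code < 0:
                raise NexusError(f"bad nucleotide symbol {s!r}")
            return code
        return decode_state(s)

    values = np.zeros((ntax, nchar), np.int16)
    for r, row in enumerate(cells):
        if len(row) != nchar:
            raise NexusError(
                f"taxon {taxa[r]!r}: expected {nchar} states, found {len(row)}"
            )
        for k, s in enumerate(row):
            values[r, k] = decode_cell(chars[k], s)

    ancestor = None
    paup = blocks.get("PAUP", "")
    ma = re.search(r"ANCSTATES\s+\S+\s+VECTOR\s*=\s*(\S+)\s*;", paup, re.IGNORECASE)
    if ma:
        vec = ma.group(1)
        if len(vec) != nchar:
            raise NexusError("ANCSTATES vector length mismatch")
        ancestor = np.array(
            [decode_cell(chars[k], s) for k, s in enumerate(vec)], np.int16
        )

    return CharacterMatrix(list(taxa), chars, values, ancestor)
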