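"""Sequence+structure coding and alignment.

A structured sequence is recoded into a 12-letter alphabet, the cross
product of nucleotide identity (A, C, G, U) and structural state (opening a
pair, unpaired, closing a pair):

    state:      open  unpaired  close
    A            A       B       C
    C            D       E       F
    G            G       H       I
    U            J       K       L

IUPAC ambiguity codes are not representable and map to ``?`` (they score 0
against everything and never open or close a helix).  The coding is
bijective per position for unambiguous input; base pairing is recovered
from the coded string by bracket matching over the open/close letters.

Alignment is global Needleman-Wunsch with affine gaps (pairwise) extended
progressively along a guide tree (profile-profile) for multiple sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import PairTable, SequenceRecord, StructuredSequence

__all__ = [
    "ALPHABET12",
    "CodedSequence",
    "AlignedRow",
    "StructuralAlignment",
    "ScoringScheme",
    "encode_12letter",
    "decode_12letter",
    "align_pairwise",
    "align_progressive",
]

NUCS = "ACGU"
STATES = ("open", "unpaired", "close")
ALPHABET12 = "ABCDEFGHIJKL"

_ENC = {}
for ni, nuc in enumerate(NUCS):
    for si, state in enumerate(STATES):
        _ENC[(nuc, state)] = ALPHABET12[3 * ni + si]
_DEC = {v: k for k, v in _ENC.items()}
OPEN_LETTERS = frozenset(_ENC[(n, "open")] for n in NUCS)
CLOSE_LETTERS = frozenset(_ENC[(n, "close")] for n in NUCS)


@dataclass
class CodedSequence:
    """A 12-letter coded sequence (plus ``?`` ambiguous, ``-`` gap)."""

    id: str
    code: str

    def __post_init__(self):
        ok = set(ALPHABET12) | {"?", "-"}
        for pos, ch in enumerate(self.code):
            if ch not in ok:
                raise ValueError(f"invalid coded character {ch!r} at position {pos}")

    def __len__(self):
        return len(self.code)


def encode_12letter(ss: StructuredSequence) -> CodedSequence:
    """Encode nucleotide x structural-state into the 12-letter alphabet."""
    partner = ss.structure.partner
    out = []
    for i, nuc in enumerate(ss.residues):
        if nuc not in NUCS:
            out.append("?")
            continue
        j = partner[i]
        state = "unpaired" if j is None else ("open" if j > i else "close")
        out.append(_ENC[(nuc, state)])
    return CodedSequence(ss.id, "".join(out))


def decode_12letter(cs: CodedSequence) -> tuple[str, str]:
    """Invert the coding: returns (sequence, dot-bracket).

    ``?`` decodes to N unpaired; ``-`` is not allowed (degap first).
    Unbalanced open/close letters raise ``ValueError``.
    """
    seq, db = [], []
    depth = 0
    for pos, ch in enumerate(cs.code):
        if ch == "-":
            raise ValueError("cannot decode a gapped code string; degap first")
        if ch == "?":
            seq.append("N")
            db.append(".")
            continue
        nuc, state = _DEC[ch]
        seq.append(nuc)
        if state == "open":
            db.append("(")
            depth += 1
        elif state == "close":
            if depth == 0:
                raise ValueError(f"unbalanced code: close letter at position {pos}")
            db.append(")")
            depth -= 1
        else:
            db.append(".")
    if depth != 0:
        raise ValueError(f"unbalanced code: {depth} unmatched open letters")
    return "".join(seq), "".join(db)


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------

@dataclass
class AlignedRow:
    """One gapped row: sequence and structure strings of equal width."""

    id: str
    seq: str
    struct: str

    def __post_init__(self):
        if len(self.seq) != len(self.struct):
            raise ValueError(f"row {self.id!r}: seq/struct width mismatch")

    def degapped(self) -> tuple[str, str]:
        seq = "".join(c for c in self.seq if c != "-")
        db = "".join(s for c, s in zip(self.seq, self.struct) if c != "-")
        return seq, db

    def pair_columns(self) -> list[tuple[int, int]]:
        """This row's base pairs in alignment-column coordinates."""
        stack, out = [], []
        for i, ch in enumerate(self.struct):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.append((stack.pop(), i))
        out.sort()
        return out

    def coded(self) -> str:
        """Gapped 12-letter code for this row."""
        seq, db = self.degapped()
        ss = StructuredSequence(
            SequenceRecord(self.id, seq), PairTable.from_dotbracket(db)
        )
        code = encode_12letter(ss).code
        out, k = [], 0
        for c in self.seq:
            if c == "-":
                out.append("-")
            else:
                out.append(code[k])
                k += 1
        return "".join(out)


class StructuralAlignment:
    """Equal-width gapped rows of sequence+structure, optional consensus."""

    def __init__(self, rows: list[AlignedRow], consensus_db: str | None = None):
        if not rows:
            raise ValueError("alignment needs at least one row")
        widths = {len(r.seq) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"ragged rows: widths {sorted(widths)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        self.rows = rows
        self.width = widths.pop()
        self.consensus_db = consensus_db
        if consensus_db is not None and len(consensus_db) != self.width:
            raise ValueError("consensus structure width mismatch")

    @classmethod
    def from_structured(cls, sseqs: list[StructuredSequence]) -> "StructuralAlignment":
        """Ungapped alignment from equal-length structured sequences."""
        rows = [
            AlignedRow(ss.id, ss.residues, ss.structure.to_dotbracket())
            for ss in sseqs
        ]
        return cls(rows)

    @classmethod
    def from_coded(cls, coded_rows: list[tuple[str, str]]) -> "StructuralAlignment":
        """Build from (id, gapped 12-letter code) rows."""
        rows = []
        for rid, code in coded_rows:
            degapped = code.replace("-", "")
            seq, db = decode_12letter(CodedSequence(rid, degapped))
            s_out, d_out, k = [], [], 0
            for ch in code:
                if ch == "-":
                    s_out.append("-")
                    d_out.append(".")
                else:
                    s_out.append(seq[k])
                    d_out.append(db[k])
                    k += 1
            rows.append(AlignedRow(rid, "".join(s_out), "".join(d_out)))
        return cls(rows)

    def ids(self):
        return [r.id for r in self.rows]

    def row(self, rid: str) -> AlignedRow:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def nucleotide_rows(self) -> list[tuple[str, str]]:
        return [(r.id, r.seq) for r in self.rows]

    def coded_rows(self) -> list[tuple[str, str]]:
        return [(r.id, r.coded()) for r in self.rows]

    def __eq__(self, other):
        return (
            isinstance(other, StructuralAlignment)
            and [(r.id, r.seq, r.struct) for r in self.rows]
            == [(r.id, r.seq, r.struct) for r in other.rows]
        )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _default_matrix() -> dict:
    """+3 identity; +1 same nucleotide or same structural state; -1 else."""
    mat = {}
    for a in ALPHABET12:
        na, sa = _DEC[a]
        for b in ALPHABET12:
            nb, sb = _DEC[b]
            if a == b:
                s = 3.0
            elif na == nb or sa == sb:
                s = 1.0
            else:
                s = -1.0
            mat[(a, b)] = s
    return mat


@dataclass
class ScoringScheme:
    """12x12 substitution scores with affine gap costs.

    ``?`` scores 0 against everything.  The table must be symmetric and
    every diagonal entry must dominate its row (identity is never worse
    than substitution).
    """

    matrix: dict = field(default_factory=_default_matrix)
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        for (a, b), s in self.matrix.items():
            if abs(self.matrix[(b, a)] - s) > 1e-12:
                raise ValueError(f"scoring matrix not symmetric at ({a}, {b})")
        for a in ALPHABET12:
            diag = self.matrix[(a, a)]
            for b in ALPHABET12:
                if self.matrix[(a, b)] > diag + 1e-12:
                    raise ValueError(
                        f"diagonal dominance violated: s({a},{b}) > s({a},{a})"
                    )
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")

    def score(self, a: str, b: str) -> float:
        if a == "?" or b == "?":
            return 0.0
        return self.matrix[(a, b)]


# ---------------------------------------------------------------------------
# Pairwise alignment (Gotoh, affine gaps)
# ---------------------------------------------------------------------------

def align_pairwise(a: CodedSequence, b: CodedSequence, scheme: ScoringScheme | None = None):
    """Optimal global alignment of two coded sequences.

    Returns ``(aligned_a, aligned_b, score)``.  A gap of length L costs
    ``gap_open + gap_extend * (L - 1)``.  Ties prefer match/mismatch, then
    a gap in ``a``, then a gap in ``b`` (fixed, documented order).
    """
    if scheme is None:
        scheme = ScoringScheme()
    A, B = a.code, b.code
    if not A or not B:
        raise ValueError("empty input sequence")
    ga, gb, sc = _profile_align([A], [B], scheme)
    return ga[0], gb[0], sc


def _profile_align(prof_a: list[str], prof_b: list[str], scheme: ScoringScheme):
    """Gotoh alignment of two profiles (lists of equal-width gapped rows).

    Column score is the average pairwise letter score; a gap character
    inside a profile scores 0 against anything (like ``?``).  Returns the
    two gapped profiles and the alignment score.
    """
    n, m = len(prof_a[0]), len(prof_b[0])
    NEG = -1e30
    go, ge = scheme.gap_open, scheme.gap_extend

    cols_a = [[row[i] for row in prof_a] for i in range(n)]
    cols_b = [[row[j] for row in prof_b] for j in range(m)]

    def colscore(ca, cb):
        tot = 0.0
        cnt = 0
        for x in ca:
            for y in cb:
                if x != "-" and y != "-":
                    tot += scheme.score(x, y)
                cnt += 1
        return tot / cnt

    # M: a[i-1] ~ b[j-1]; X: gap in a (consumes b); Y: gap in b (consumes a)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        Y[i][0] = go + ge * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore(cols_a[i - 1], cols_b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + ge, Y[i][j - 1] + go)
            Y[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + go, Y[i - 1][j] + ge)

    score = max(M[n][m], X[n][m], Y[n][m])
    # traceback with tie preference M > X (gap in a) > Y (gap in b)
    i, j = n, m
    if M[i][j] >= X[i][j] - 1e-12 and M[i][j] >= Y[i][j] - 1e-12:
        state = "M"
    elif X[i][j] >= Y[i][j] - 1e-12:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = colscore(cols_a[i - 1], cols_b[j - 1])
            prev = M[i][j] - s
            out_a.append("col")
            out_b.append("col")
            i, j = i - 1, j - 1
            if abs(M[i][j] - prev) < eps:
                state = "M"
            elif abs(X[i][j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X" and j > 0:
            val = X[i][j]
            out_a.append("gap")
            out_b.append("col")
            if i == 0:
                j -= 1
                state = "X"
                continue
            if abs(M[i][j - 1] + go - val) < eps:
                state = "M"
            elif abs(X[i][j - 1] + ge - val) < eps:
                state = "X"
            else:
                state = "Y"
            j -= 1
        elif state == "Y" and i > 0:
            val = Y[i][j]
            out_a.append("col")
            out_b.append("gap")
            if j == 0:
                i -= 1
                state = "Y"
                continue
            if abs(M[i - 1][j] + go - val) < eps:
                state = "M"
            elif abs(X[i - 1][j] + go - val) < eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # boundary
            state = "X" if j > 0 else "Y"
    out_a.reverse()
    out_b.reverse()

    res_a = ["" for _ in prof_a]
    res_b = ["" for _ in prof_b]
    ia = ib = 0
    for oa, ob in zip(out_a, out_b):
        if oa == "col":
            for r, row in enumerate(prof_a):
                res_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(prof_a)):
                res_a[r] += "-"
        if ob == "col":
            for r, row in enumerate(prof_b):
                res_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(prof_b)):
                res_b[r] += "-"
    return res_a, res_b, float(score)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    def counts(s):
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            d[w] = d.get(w, 0) + 1
        return d

    ca, cb = counts(a), counts(b)
    shared = sum(min(ca.get(w, 0), cb.get(w, 0)) for w in ca)
    denom = max(1, min(len(a), len(b)) - k + 1)
    return 1.0 - shared / denom


def align_progressive(seqs: list[CodedSequence], scheme=None, guide=None, seed: int = 0):
    """Progressive profile-profile alignment along a guide tree.

    Without an explicit guide tree one is built from 12-letter k-mer
    distances by neighbour joining.  Merge order is the guide tree's
    postorder with deterministic child ordering, so the result is invariant
    to the input order of the sequences (up to row order).

    Returns a :class:`StructuralAlignment` whose rows are in input order.
    """
    import warnings

    if scheme is None:
        scheme = ScoringScheme()
    if len(seqs) < 2:
        warnings.warn("align_progressive called with a single sequence")
        return StructuralAlignment.from_coded([(seqs[0].id, seqs[0].code)])
    byid = {s.id: s for s in seqs}
    if len(byid) != len(seqs):
        raise ValueError("duplicate sequence ids")
    if guide is None:
        from .phylo import nj_tree

        labels = sorted(byid)
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = _kmer_distance(byid[labels[i]].code, byid[labels[j]].code)
                D[i, j] = D[j, i] = d
        guide = nj_tree(D, labels) if n >= 3 else None

    if guide is None:  # two sequences
        a, b = seqs
        ga, gb, _ = align_pairwise(a, b, scheme)
        return StructuralAlignment.from_coded([(a.id, ga), (b.id, gb)])

    # postorder merge along the guide tree
    def merge(node):
        if node.is_leaf():
            lab = node.taxon.label
            return [lab], [byid[lab].code]
        parts = [merge(ch) for ch in node.child_nodes()]
        parts.sort(key=lambda p: p[0][0])  # deterministic merge order
        ids, prof = parts[0]
        for ids2, prof2 in parts[1:]:
            pa, pb, _ = _profile_align(prof, prof2, scheme)
            ids = ids + ids2
            prof = pa + pb
        return ids, prof

    ids, prof = merge(guide.seed_node)
    rowmap = dict(zip(ids, prof))
    order = [s.id for s in seqs]
    return StructuralAlignment.from_coded([(rid, rowmap[rid]) for rid in order])
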