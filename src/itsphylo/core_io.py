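"""Readers and writers for the formats the pipeline touches.

Sequences are normalised to the RNA alphabet internally (T -> U, uppercase);
whether a record arrived as DNA is remembered so FASTA output can restore the
original alphabet.  Coordinates are 0-based half-open internally; each file
format keeps its native convention at the boundary.

Formats: multi-record FASTA, Vienna dot-bracket triplets (with an optional
trailing free-energy annotation), Stockholm 1.0 with a ``#=GC SS_cons``
consensus-structure line and optional per-row ``#=GR <id> SS`` lines, Newick
with numeric internal-node labels read as clade support, and a YAML
key/value configuration file.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import dendropy
import yaml

__all__ = [
    "SequenceRecord",
    "PairTable",
    "StructuredSequence",
    "read_fasta",
    "write_fasta",
    "read_dotbracket",
    "write_dotbracket",
    "read_stockholm_struct_aln",
    "write_stockholm_struct_aln",
    "read_newick",
    "write_newick",
    "read_config",
    "DEFAULT_CONFIG",
    "IUPAC_RNA",
    "AMBIGUITY_MAP",
]

# IUPAC nucleotide codes on the RNA alphabet (input may use T; normalised).
IUPAC_RNA = set("ACGURYSWKMBDHVN")

# Ambiguity code -> set of concrete nucleotides.
AMBIGUITY_MAP = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named nucleotide sequence, stored on the RNA alphabet."""

    id: str
    residues: str
    description: str = ""
    was_dna: bool = False

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        norm = self.residues.upper()
        if "T" in norm:
            self.was_dna = True
            norm = norm.replace("T", "U")
        for pos, ch in enumerate(norm):
            if ch not in IUPAC_RNA:
                raise FormatError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos}"
                )
        self.residues = norm

    def __len__(self) -> int:
        return len(self.residues)


class PairTable:
    """Nested (pseudoknot-free) base-pairing of a sequence of given length.

    ``partner[i]`` is the 0-based partner of position ``i`` or ``None``.
    Invariants checked on construction: symmetry, no self pairs, pairs
    non-crossing, and ``|i - j| >= min_loop + 1``.
    """

    __slots__ = ("length", "partner")

    def __init__(self, partner, min_loop: int = 0):
        partner = list(partner)
        self.length = len(partner)
        self.partner = partner
        seen_open: list[int] = []
        for i, j in enumerate(partner):
            if j is None:
                continue
            if not 0 <= j < self.length:
                raise FormatError(f"partner of {i} out of range: {j}")
            if j == i:
                raise FormatError(f"position {i} pairs with itself")
            if partner[j] != i:
                raise FormatError(f"asymmetric pairing at ({i}, {j})")
            if j > i and j - i < min_loop + 1:
                raise FormatError(
                    f"pair ({i}, {j}) closes a loop shorter than min_loop={min_loop}"
                )
        # non-crossing check via bracket discipline
        stack: list[int] = []
        for i, j in enumerate(partner):
            if j is None:
                continue
            if j > i:
                stack.append(j)
            else:
                if not stack or stack[-1] != i:
                    raise FormatError(f"crossing (pseudoknotted) pair ({j}, {i})")
                stack.pop()

    @classmethod
    def from_dotbracket(cls, db: str, min_loop: int = 0) -> "PairTable":
        partner: list[int | None] = [None] * len(db)
        stack: list[int] = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise FormatError(
                        f"unbalanced structure: unmatched ')' at position {i}"
                    )
                j = stack.pop()
                partner[j] = i
                partner[i] = j
            elif ch not in ".":
                raise FormatError(f"invalid structure character {ch!r} at position {i}")
        if stack:
            raise FormatError(
                f"unbalanced structure: {len(stack)} unmatched '(' "
                f"(first at position {stack[0]})"
            )
        return cls(partner, min_loop=min_loop)

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j is None else ("(" if j > i else ")"))
        return "".join(out)

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, ordered by i."""
        return [(i, j) for i, j in enumerate(self.partner) if j is not None and j > i]

    def n_pairs(self) -> int:
        return len(self.pairs())

    def __eq__(self, other):
        return isinstance(other, PairTable) and self.partner == other.partner

    def __repr__(self):
        return f"PairTable({self.to_dotbracket()!r})"


@dataclass
class StructuredSequence:
    """A sequence together with its secondary structure and optional ΔG."""

    record: SequenceRecord
    structure: PairTable
    delta_g: float | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.structure.length != len(self.record):
            raise FormatError(
                f"structure length {self.structure.length} != sequence length "
                f"{len(self.record)} for {self.record.id!r}"
            )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def residues(self) -> str:
        return self.record.residues


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _as_lines(path_or_stream):
    if hasattr(path_or_stream, "read"):
        return path_or_stream.read().splitlines()
    with open(path_or_stream) as fh:
        return fh.read().splitlines()


def read_fasta(path_or_stream) -> list[SequenceRecord]:
    """Parse a multi-record FASTA file into :class:`SequenceRecord` objects.

    Parsing is delegated to Biopython; validation (duplicate ids, empty
    sequences, non-IUPAC characters) happens on top of it.
    """
    from Bio import SeqIO

    if hasattr(path_or_stream, "read"):
        handle = path_or_stream
        records_iter = SeqIO.parse(handle, "fasta")
        bio_records = list(records_iter)
    else:
        with open(path_or_stream) as fh:
            bio_records = list(SeqIO.parse(fh, "fasta"))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in bio_records:
        if rec.id in seen:
            raise FormatError(f"duplicate id: {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(records, path_or_stream=None, width: int = 60) -> str:
    """Write records as FASTA; DNA-origin records are written back with T."""
    out = io.StringIO()
    for rec in records:
        desc = f" {rec.description}" if rec.description else ""
        out.write(f">{rec.id}{desc}\n")
        seq = rec.residues.replace("U", "T") if rec.was_dna else rec.residues
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    text = out.getvalue()
    if path_or_stream is not None:
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Vienna dot-bracket
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"^(?P<db>[().]+)(?:\s+\((?P<dg>-?\d+(?:\.\d+)?)\))?\s*$")


def read_dotbracket(path_or_stream) -> list[StructuredSequence]:
    """Parse Vienna triplets: ``>id`` / sequence / dot-bracket [ (ΔG) ]."""
    lines = [ln for ln in _as_lines(path_or_stream) if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError("dot-bracket file must consist of >id/sequence/structure triplets")
    out: list[StructuredSequence] = []
    for k in range(0, len(lines), 3):
        hdr, seq, struct = lines[k], lines[k + 1].strip(), lines[k + 2].strip()
        if not hdr.startswith(">"):
            raise FormatError(f"expected '>' header at line {k + 1}, got {hdr!r}")
        parts = hdr[1:].strip().split(None, 1)
        rid = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        m = _ENERGY_RE.match(struct)
        if not m:
            raise FormatError(f"malformed structure line for {rid!r}: {struct!r}")
        db = m.group("db")
        dg = float(m.group("dg")) if m.group("dg") is not None else None
        rec = SequenceRecord(rid, seq, desc)
        if len(db) != len(rec):
            raise FormatError(
                f"{rid!r}: structure length {len(db)} != sequence length {len(rec)}"
            )
        out.append(StructuredSequence(rec, PairTable.from_dotbracket(db), delta_g=dg))
    if not out:
        raise FormatError("no dot-bracket records found")
    return out


def write_dotbracket(sseqs, path_or_stream=None) -> str:
    out = io.StringIO()
    for ss in sseqs:
        desc = f" {ss.record.description}" if ss.record.description else ""
        out.write(f">{ss.id}{desc}\n{ss.residues}\n{ss.structure.to_dotbracket()}")
        if ss.delta_g is not None:
            out.write(f" ({ss.delta_g:.2f})")
        out.write("\n")
    text = out.getvalue()
    if path_or_stream is not None:
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Stockholm structural alignments
# ---------------------------------------------------------------------------

def read_stockholm_struct_aln(path_or_stream):
    """Read a Stockholm 1.0 alignment with a consensus-structure line.

    Per-row ``#=GR <id> SS`` lines are used when present; otherwise each
    row's structure is projected from the ``#=GC SS_cons`` consensus (a
    consensus pair survives in a row iff both columns are non-gap there).
    Returns a :class:`itsphylo.struct_align.StructuralAlignment`.
    """
    from io import StringIO

    from Bio import AlignIO

    from .struct_align import AlignedRow, StructuralAlignment

    text = "\n".join(_as_lines(path_or_stream)) + "\n"
    if not text.startswith("# STOCKHOLM"):
        raise FormatError("missing '# STOCKHOLM 1.0' header")
    try:
        bio_aln = AlignIO.read(StringIO(text), "stockholm")
    except ValueError as exc:
        raise FormatError(f"ragged alignment rows or repeated identifier: {exc}") from exc
    if len(bio_aln) == 0:
        raise FormatError("no alignment rows found")
    width = bio_aln.get_alignment_length()
    ss_cons = bio_aln.column_annotations.get("secondary_structure")
    if ss_cons is None:
        raise FormatError("missing #=GC SS_cons consensus-structure line")
    cons_db = ss_cons.replace("-", ".").replace("_", ".").replace(",", ".").replace(":", ".")
    cons_pt = PairTable.from_dotbracket(cons_db)  # raises on unbalanced consensus

    aligned_rows = []
    for rec in bio_aln:
        rid = rec.id
        seq = str(rec.seq).upper().replace("T", "U").replace(".", "-")
        gr = rec.letter_annotations.get("secondary_structure")
        if gr:
            st = gr.replace("-", ".")
            if len(st) != width:
                raise FormatError(f"#=GR SS length mismatch for row {rid!r}")
            PairTable.from_dotbracket(st)
        else:
            # project the consensus onto this row
            chars = ["."] * width
            for i, j in cons_pt.pairs():
                if seq[i] != "-" and seq[j] != "-":
                    chars[i], chars[j] = "(", ")"
            st = "".join(chars)
        aligned_rows.append(AlignedRow(rid, seq, st))
    return StructuralAlignment(aligned_rows, consensus_db=cons_db)


def write_stockholm_struct_aln(aln, path_or_stream=None) -> str:
    """Write a StructuralAlignment as Stockholm 1.0 (deterministic layout)."""
    name_w = max(len(r.id) for r in aln.rows)
    name_w = max(name_w, len("#=GR x SS"))
    out = io.StringIO()
    out.write("# STOCKHOLM 1.0\n")
    for r in aln.rows:
        out.write(f"{r.id:<{name_w}} {r.seq}\n")
        out.write(f"{'#=GR ' + r.id + ' SS':<{name_w}} {r.struct}\n")
    cons = aln.consensus_db if aln.consensus_db is not None else "." * aln.width
    out.write(f"{'#=GC SS_cons':<{name_w}} {cons}\n//\n")
    text = out.getvalue()
    if path_or_stream is not None:
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree; numeric internal-node labels become ``node.support``.

    ``source`` may be a path, an open stream, or a Newick string.
    """
    if hasattr(source, "read"):
        data = source.read()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            data = fh.read()
    else:
        data = str(source)
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # normalise dendropy's parser errors
        msg = str(exc)
        if "Duplicate taxon" in msg or "Multiple occurrences" in msg:
            dup = msg.rstrip().rsplit(":", 1)[-1].strip()
            raise FormatError(f"duplicate leaf {dup}") from exc
        raise FormatError(f"malformed Newick: {msg}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate leaf {lab}")
        seen.add(lab)
    for nd in tree.preorder_node_iter():
        nd.support = None
        if not nd.is_leaf() and nd.label is not None:
            try:
                nd.support = float(nd.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree; ``node.support`` values become internal labels."""
    for nd in tree.preorder_node_iter():
        sup = getattr(nd, "support", None)
        if not nd.is_leaf() and sup is not None:
            nd.label = f"{sup:.6g}"
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
        unquoted_underscores=True,
    )
    return s.strip() + "\n" if not s.endswith("\n") else s


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "min_loop": 3,
    "energy_band_percent": 5.0,
    "max_interior_loop": 30,
    "motif": "UGGU",
    "motif_window": 10,
    "min_hybrid_pairs": 6,
    "pair_threshold": 0.5,
    "gap_open": -5.0,
    "gap_extend": -1.0,
    "bootstrap_reps": 1000,
    "support_cutoff": 0.5,
    "posterior_cutoff": 0.95,
    "max_distance": 5.0,
    "seed": 0,
    "rate_matrix": None,  # optional explicit GTR rate matrix (4x4 rows)
}


def read_config(path_or_stream=None, warn=None) -> dict:
    """Load a YAML config, fill defaults, and validate numeric tables.

    Unknown keys produce a warning (via ``warn`` callable or ``warnings``);
    a rate matrix that is not square raises ``FormatError``.
    """
    import warnings

    if warn is None:
        warn = lambda msg: warnings.warn(msg, stacklevel=2)
    raw = {}
    if path_or_stream is not None:
        text = (
            path_or_stream.read()
            if hasattr(path_or_stream, "read")
            else open(path_or_stream).read()
        )
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    cfg = dict(DEFAULT_CONFIG)
    for key, value in raw.items():
        if key not in DEFAULT_CONFIG:
            warn(f"unknown config key: {key!r}")
            continue
        cfg[key] = value
    if cfg["rate_matrix"] is not None:
        mat = cfg["rate_matrix"]
        n = len(mat)
        if any(len(row) != n for row in mat):
            raise FormatError(
                f"rate_matrix must be square; got {n} rows of lengths "
                f"{[len(r) for r in mat]}"
            )
    for key in ("min_loop", "motif_window", "min_hybrid_pairs", "bootstrap_reps"):
        if not isinstance(cfg[key], int) or cfg[key] < 0:
            raise FormatError(f"config key {key!r} must be a non-negative integer")
    return cfg
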