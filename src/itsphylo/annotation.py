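"""Structure annotation: helices, ITS2 hallmark checks, structural variants
and consensus structure models.

The ITS1 secondary structure in birches decomposes into four main helices
(H1-H4) radiating from a central loop, plus an occasional low-stability
extra helix (Ha); ITS2 shows the canonical four-helix architecture with a
conserved motif on the 5' arm of helix III, a pyrimidine (U-U) mismatch in
helix II, and a proximal stem formed by hybridisation of the 5.8S 3' end
with the 28S 5' end.  This module implements those checks against predicted
structures and builds genus-level consensus models across a structural
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import PairTable, StructuredSequence
from .folding import is_valid_pair

__all__ = [
    "Helix",
    "HallmarkReport",
    "VariantCatalogue",
    "ConsensusStructure",
    "decompose_helices",
    "label_helices",
    "check_its2_hallmarks",
    "select_structure",
    "classify_helix_variants",
    "build_consensus_structure",
]


@dataclass
class Helix:
    """A stem: nested pairs between two branching points.

    Bulges and internal loops of any size do not split a helix; only
    multiloop branching (or a terminal loop) does.
    """

    index: int                      # 1-based, 5'->3' by opening position
    pairs: list                     # [(i, j), ...] outermost first
    label: str | None = None        # H1..H4, Ha, ...
    pair_runs: list = field(default_factory=list)   # runs of contiguously stacked pairs
    internal_loops: list = field(default_factory=list)  # [(size_left, size_right), ...]

    @property
    def span(self):
        return self.pairs[0]

    @property
    def n_pairs(self):
        return len(self.pairs)

    @property
    def apex(self):
        """Innermost pair (closest to the terminal loop / branch point)."""
        return self.pairs[-1]


def decompose_helices(structure: PairTable) -> list[Helix]:
    """Partition the pairs of a nested structure into helices.

    A pair continues its parent's helix iff the parent encloses exactly one
    pair directly; otherwise it opens a new helix.  Helices are numbered
    5'->3' by their outermost opening position.  Every pair belongs to
    exactly one helix.
    """
    pairs = structure.pairs()
    partner = structure.partner
    parent: dict[tuple, tuple | None] = {}
    children: dict[tuple | None, list] = {None: []}
    stack: list[tuple] = []
    for i in range(structure.length):
        j = partner[i]
        if j is None:
            continue
        if j > i:
            par = stack[-1] if stack else None
            parent[(i, j)] = par
            children.setdefault(par, []).append((i, j))
            children.setdefault((i, j), [])
            stack.append((i, j))
        else:
            stack.pop()

    helices: list[Helix] = []
    helix_of: dict[tuple, Helix] = {}
    for p in pairs:  # ordered by opening position
        par = parent[p]
        if par is not None and len(children[par]) == 1:
            h = helix_of[par]
            h.pairs.append(p)
        else:
            h = Helix(index=len(helices) + 1, pairs=[p])
            helices.append(h)
        helix_of[p] = h

    for h in helices:
        runs, loops = [], []
        run = [h.pairs[0]]
        for prev, cur in zip(h.pairs, h.pairs[1:]):
            left = cur[0] - prev[0] - 1
            right = prev[1] - cur[1] - 1
            if left == 0 and right == 0:
                run.append(cur)
            else:
                loops.append((left, right))
                runs.append(run)
                run = [cur]
        runs.append(run)
        h.pair_runs = runs
        h.internal_loops = loops
    return helices


def label_helices(helices: list[Helix], n_main: int = 4) -> list[Helix]:
    """Assign H1..Hn labels positionally to top-level helices.

    With more helices than ``n_main``, the ``n_main`` largest (by pair
    count) take the main labels in positional order and the remainder are
    flagged as additional helices (Ha, Hb, ...), matching the convention of
    an optional low-stability extra helix.
    """
    if len(helices) <= n_main:
        for k, h in enumerate(helices, 1):
            h.label = f"H{k}"
        return helices
    ranked = sorted(helices, key=lambda h: (-h.n_pairs, h.span[0]))
    main = set(id(h) for h in ranked[:n_main])
    k = 0
    extra = 0
    for h in helices:
        if id(h) in main:
            k += 1
            h.label = f"H{k}"
        else:
            h.label = "H" + "abcdefgh"[extra]
            extra += 1
    return helices


@dataclass
class HallmarkReport:
    """Outcome of the ITS2 correctness checks."""

    motif_found: bool | None = None
    motif_position: int | None = None
    uu_mismatch_found: bool | None = None
    uu_position: int | None = None
    hybrid_stem_ok: bool | None = None
    hybrid_stem_length: int | None = None
    reasons: list = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        checks = [self.motif_found, self.uu_mismatch_found, self.hybrid_stem_ok]
        enabled = [c for c in checks if c is not None]
        return all(enabled) if enabled else False


def _top_level(helices: list[Helix], structure: PairTable) -> list[Helix]:
    """Helices whose outermost pair is not enclosed by any other pair."""
    out = []
    for h in helices:
        i, j = h.span
        enclosed = any(
            a < i and j < b for a, b in structure.pairs() if (a, b) != (i, j)
        )
        if not enclosed:
            out.append(h)
    return out


def check_its2_hallmarks(
    ss: StructuredSequence,
    flank_5_8S: str | None = None,
    flank_28S: str | None = None,
    motif: str = "UGGU",
    motif_window: int = 10,
    min_hybrid_pairs: int = 6,
) -> HallmarkReport:
    """Check the three ITS2 correctness hallmarks on a predicted structure.

    (a) the conserved motif (default ``UGGU``) on the 5' strand of helix 3
    within ``motif_window`` nt of its apex; (b) a 1x1 U-U internal loop
    within helix 2; (c) at least ``min_hybrid_pairs`` consecutive canonical
    pairs between the 3' end of the 5.8S flank and the 5' end of the 28S
    flank.  The flank check is skipped (reported ``None``) when flanks are
    not supplied.
    """
    rep = HallmarkReport()
    seq = ss.residues
    helices = label_helices(_top_level(decompose_helices(ss.structure), ss.structure))

    def helix(lbl):
        for h in helices:
            if h.label == lbl:
                return h
        return None

    h3 = helix("H3")
    if h3 is None:
        rep.motif_found = False
        rep.reasons.append("motif: helix absent")
    else:
        i_outer = h3.span[0]
        i_inner = h3.apex[0]
        lo = max(i_outer, i_inner - motif_window + 1)
        segment = seq[lo : i_inner + len(motif)]
        pos = segment.find(motif)
        rep.motif_found = pos >= 0
        rep.motif_position = lo + pos if pos >= 0 else None
        if pos < 0:
            rep.reasons.append(f"motif {motif!r} not on helix-3 5' arm near apex")

    h2 = helix("H2")
    if h2 is None:
        rep.uu_mismatch_found = False
        rep.reasons.append("U-U: helix absent")
    else:
        rep.uu_mismatch_found = False
        for prev, cur in zip(h2.pairs, h2.pairs[1:]):
            left = cur[0] - prev[0] - 1
            right = prev[1] - cur[1] - 1
            if left == 1 and right == 1 and seq[prev[0] + 1] == "U" and seq[prev[1] - 1] == "U":
                rep.uu_mismatch_found = True
                rep.uu_position = prev[0] + 1
                break
        if not rep.uu_mismatch_found:
            rep.reasons.append("no 1x1 U-U internal loop in helix 2")

    if flank_5_8S is not None and flank_28S is not None:
        f58 = str(flank_5_8S).upper().replace("T", "U")
        f28 = str(flank_28S).upper().replace("T", "U")
        best = run = 0
        for k in range(min(len(f58), len(f28))):
            if is_valid_pair(f58[-1 - k], f28[k]):
                run += 1
                best = max(best, run)
            else:
                run = 0
        rep.hybrid_stem_length = best
        rep.hybrid_stem_ok = best >= min_hybrid_pairs
        if not rep.hybrid_stem_ok:
            rep.reasons.append(
                f"hybrid stem only {best} consecutive pairs (< {min_hybrid_pairs})"
            )
    return rep


def select_structure(
    candidates,
    ss_record=None,
    flank_5_8S=None,
    flank_28S=None,
    **hallmark_params,
) -> StructuredSequence:
    """Pick the lowest-ΔG candidate structure passing the hallmark checks.

    ``candidates`` is a FoldResult (its MFE structure plus alternates) or an
    explicit list of ``(PairTable, delta_g)``.  If no candidate passes, the
    MFE structure is returned flagged ``"unverified"``.
    """
    from .folding import FoldResult

    if isinstance(candidates, FoldResult):
        if ss_record is None:
            raise ValueError("ss_record required when passing a FoldResult")
        cands = [(candidates.structure, candidates.delta_g)] + list(candidates.alternates)
    else:
        cands = list(candidates)
    if not cands:
        raise ValueError("empty candidate list")
    if ss_record is None:
        raise ValueError("ss_record (the SequenceRecord) is required")
    cands = sorted(cands, key=lambda t: t[1])
    for pt, dg in cands:
        ss = StructuredSequence(ss_record, pt, delta_g=dg)
        rep = check_its2_hallmarks(ss, flank_5_8S, flank_28S, **hallmark_params)
        if rep.overall_pass:
            return ss
    mfe = min(cands, key=lambda t: t[1])
    ss = StructuredSequence(ss_record, mfe[0], delta_g=mfe[1])
    ss.flags.add("unverified")
    return ss


@dataclass
class VariantCatalogue:
    """Structural variants of one helix across a set of sequences."""

    helix_label: str
    variants: list  # [(variant_id, canonical_structure, [member ids])]

    def members(self, variant_id: str) -> list:
        for vid, _, mem in self.variants:
            if vid == variant_id:
                return mem
        raise KeyError(variant_id)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def classify_helix_variants(aln, helix_label: str) -> VariantCatalogue:
    """Group alignment rows by the shape of one helix.

    Each row's gap-stripped structure is decomposed into labelled helices;
    rows are grouped by exact identity of the helix's dot-bracket substring
    (structure only; sequence differences are ignored).  Variant ids A, B,
    C... are assigned by decreasing group size, ties by first occurrence.
    """
    groups: dict[str, list] = {}
    first_seen: dict[str, int] = {}
    for ridx, row in enumerate(aln.rows):
        seq, db = row.degapped()
        pt = PairTable.from_dotbracket(db)
        helices = label_helices(_top_level(decompose_helices(pt), pt))
        shape = ""
        found = False
        for h in helices:
            if h.label == helix_label:
                i, j = h.span
                shape = db[i : j + 1]
                found = True
                break
        if not found:
            shape = ""
        groups.setdefault(shape, []).append(row.id)
        first_seen.setdefault(shape, ridx)
    if all(shape == "" for shape in groups):
        raise ValueError(f"unknown helix label: {helix_label!r} (absent from every row)")
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), first_seen[kv[0]]))
    letters = [chr(ord("A") + k) for k in range(len(ordered))]
    return VariantCatalogue(
        helix_label, [(lab, shape, mem) for lab, (shape, mem) in zip(letters, ordered)]
    )


@dataclass
class ConsensusStructure:
    """Majority consensus pairing over alignment columns."""

    width: int
    pair_freq: dict            # {(i, j): frequency in [0, 1]}
    presence: list             # per-column non-gap fraction
    indel_columns: set         # columns gapped in at least one row

    def pairs(self):
        return sorted(self.pair_freq)

    def pair_table(self) -> PairTable:
        partner: list[int | None] = [None] * self.width
        for i, j in self.pair_freq:
            partner[i], partner[j] = j, i
        return PairTable(partner)

    def to_dotbracket(self) -> str:
        return self.pair_table().to_dotbracket()

    def render(self, consensus_seq: str) -> str:
        """Render a consensus sequence with indel columns in lowercase."""
        out = []
        for i, ch in enumerate(consensus_seq):
            out.append(ch.lower() if i in self.indel_columns else ch.upper())
        return "".join(out)


def build_consensus_structure(aln, pair_threshold: float = 0.5) -> ConsensusStructure:
    """Build the consensus pairing of a structural alignment.

    A column pair (i, j) enters the consensus iff the fraction of rows
    whose residues at i and j are mutually paired reaches
    ``pair_threshold``; rows gapped at i or j are excluded from the
    denominator.  Crossing candidates are resolved by keeping the
    higher-frequency pair, then the outer (larger-span) pair, so the
    consensus is always nested.  At threshold 1.0 this is exactly the
    intersection of the row structures (over ungapped rows).
    """
    if len(aln.rows) < 2:
        raise ValueError("consensus requires at least 2 rows")
    width = aln.width
    counts: dict[tuple, int] = {}
    for row in aln.rows:
        for i, j in row.pair_columns():
            counts[(i, j)] = counts.get((i, j), 0) + 1
    freqs: dict[tuple, float] = {}
    for (i, j), c in counts.items():
        denom = sum(1 for row in aln.rows if row.seq[i] != "-" and row.seq[j] != "-")
        if denom == 0:
            continue
        f = c / denom
        if f >= pair_threshold:
            freqs[(i, j)] = f
    # resolve crossings: higher frequency wins, then the outer pair
    chosen: dict[tuple, float] = {}
    used: set[int] = set()
    order = sorted(freqs.items(), key=lambda kv: (-kv[1], -(kv[0][1] - kv[0][0]), kv[0][0]))
    for (i, j), f in order:
        if i in used or j in used:
            continue
        crossing = any(
            (a < i < b < j) or (i < a < j < b) for (a, b) in chosen
        )
        if crossing:
            continue
        chosen[(i, j)] = f
        used.update((i, j))
    presence = [
        sum(1 for row in aln.rows if row.seq[c] != "-") / len(aln.rows)
        for c in range(width)
    ]
    indels = {c for c in range(width) if presence[c] < 1.0}
    return ConsensusStructure(width, chosen, presence, indels)
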