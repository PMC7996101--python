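"""Ground-truth simulation of ITS-like structured sequences on trees.

The generator mirrors the inference models: a Yule (pure-birth) tree; a
root sequence with a fixed helix layout (four main helices plus an
optional low-stability extra helix, ~250 nt by default, matching the ITS
architecture at desk scale); paired sites evolving under the 16-state
doublet chain whose single events change one nucleotide at a time — so a
hemi-compensatory change (hCBC) arises in one event and a full
compensatory change (CBC) only through two successive events on the same
pair — and unpaired sites under 4x4 GTR with a proportion of invariant
sites.  Every event is logged, and replaying the log from the root
reproduces the leaves exactly, which makes the hCBC/CBC census and the
tree-recovery tests checkable against known truth.

Indels are off by default; when enabled, deletions of unpaired columns
(geometric length) are simulated, insertions are not.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from .core_io import PairTable, SequenceRecord, StructuredSequence
from .folding import VALID_PAIRS
from .phylo import DOUBLET_STATES, NUC_STATES, SubstitutionModel
from .struct_align import AlignedRow, StructuralAlignment

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "simulate_evolution",
    "make_its2_toy",
    "default_helix_layout",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def default_helix_layout():
    """Four main helices (stem, loop) plus spacers, ~250 nt total."""
    return [(12, 5), (14, 4), (16, 6), (10, 4)]


@dataclass
class SimulationConfig:
    n_taxa: int = 8
    birth_rate: float = 1.0
    helix_layout: list = field(default_factory=default_helix_layout)
    spacer: int = 8
    extra_helix: bool = False       # small extra helix (Ha) after the first
    paired_rate: float = 1.0        # rate multiplier on doublet sites
    paired_pi: dict | None = None   # doublet -> frequency; valid pairs only
    paired_exch: float = 1.0
    unpaired_rate: float = 1.0
    p_inv: float = 0.2              # invariant fraction of unpaired sites
    indel_rate: float = 0.0         # deletions per unpaired site per unit time
    tree_scale: float = 0.1         # mean branch length rescaling
    seed: int = 0                   # mandatory; all randomness flows from it

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        for r in (self.paired_rate, self.unpaired_rate, self.indel_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimulationTruth:
    tree: dendropy.Tree
    root: StructuredSequence
    alignment: StructuralAlignment
    pairing_mask: list              # [(i, j), ...] true paired columns
    event_log: pd.DataFrame         # branch, site, from, to, pairing_preserving

    def hcbc_truth_sites(self) -> set:
        """Consensus pairs at which some leaf pair differs by a single
        pairing-preserving change (derived from leaf doublets, which the
        event log reproduces by replay)."""
        out = set()
        rows = self.alignment.rows
        for (i, j) in self.pairing_mask:
            douts = {r.seq[i] + r.seq[j] for r in rows}
            for a in douts:
                for b in douts:
                    if a < b and a in VALID_PAIRS and b in VALID_PAIRS:
                        ndiff = (a[0] != b[0]) + (a[1] != b[1])
                        if ndiff == 1:
                            out.add((i, j))
        return out

    def cbc_truth_sites(self) -> set:
        out = set()
        for (i, j) in self.pairing_mask:
            douts = {r.seq[i] + r.seq[j] for r in self.alignment.rows}
            for a in douts:
                for b in douts:
                    if a < b and a in VALID_PAIRS and b in VALID_PAIRS:
                        if (a[0] != b[0]) + (a[1] != b[1]) == 2:
                            out.add((i, j))
        return out


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree with exponential waiting times.

    After the n-th birth one further waiting time is appended so terminal
    branches are strictly positive.  Leaves are labelled T1..Tn in birth
    order; deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = random.Random(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tips = []
    for _ in range(2):
        nd = dendropy.Node()
        root.add_child(nd)
        nd.edge.length = 0.0
        tips.append(nd)
    while len(tips) < n_taxa:
        wait = rng.expovariate(birth_rate * len(tips))
        for t in tips:
            t.edge.length += wait
        k = rng.randrange(len(tips))
        parent = tips.pop(k)
        for _ in range(2):
            nd = dendropy.Node()
            parent.add_child(nd)
            nd.edge.length = 0.0
            tips.append(nd)
    tail = rng.expovariate(birth_rate * len(tips))
    for t in tips:
        t.edge.length += tail
    for lab, t in zip(labels, tips):
        t.taxon = tns.get_taxon(lab)
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def _build_root_structure(cfg: SimulationConfig):
    """Helix layout -> pair list and total length."""
    pairs = []
    pos = 0
    layout = list(cfg.helix_layout)
    if cfg.extra_helix:
        layout.insert(1, (5, 4))  # small low-stability Ha after H1
    for stem, loop in layout:
        pos += cfg.spacer
        start = pos
        length = 2 * stem + loop
        for k in range(stem):
            pairs.append((start + k, start + length - 1 - k))
        pos = start + length
    pos += cfg.spacer
    return pairs, pos


def simulate_evolution(cfg: SimulationConfig):
    """Evolve a structured root sequence over a Yule tree.

    Returns ``(leaf_records, alignment, truth)``: ungapped leaf FASTA
    records, the true StructuralAlignment (trivial when ``indel_rate`` is
    0), and a :class:`SimulationTruth` with the tree, root, pairing mask
    and per-branch event log.
    """
    rng = random.Random(cfg.seed + 1)
    tree = simulate_tree(cfg.n_taxa, cfg.birth_rate, seed=cfg.seed)
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= cfg.tree_scale

    pairs, length = _build_root_structure(cfg)
    paired_pos = {p for pr in pairs for p in pr}
    unpaired_pos = [i for i in range(length) if i not in paired_pos]

    valid = sorted(VALID_PAIRS)
    # the generative doublet chain is strictly pairing-preserving: its
    # stationary mass sits on the six canonical doublets only, so single
    # events can never reach an invalid doublet
    pi16 = np.zeros(16)
    if cfg.paired_pi is not None:
        for d, f in cfg.paired_pi.items():
            d = d.upper().replace("T", "U")
            if f > 0 and d not in VALID_PAIRS:
                raise ValueError(f"paired_pi puts mass on invalid doublet {d!r}")
            pi16[DOUBLET_STATES.index(d)] = f
    else:
        for d in valid:
            pi16[DOUBLET_STATES.index(d)] = 1.0 / 6.0
    dmodel = SubstitutionModel.doublet(pi=pi16, exch=cfg.paired_exch)
    umodel = SubstitutionModel.gtr()

    # root: doublets from the doublet stationary distribution restricted to
    # valid pairs; unpaired residues uniform.
    root_seq = ["A"] * length
    root_doublets = {}
    wts = [dmodel.pi[DOUBLET_STATES.index(d)] for d in valid]
    for (i, j) in pairs:
        d = rng.choices(valid, weights=wts)[0]
        root_seq[i], root_seq[j] = d[0], d[1]
        root_doublets[(i, j)] = d
    for i in unpaired_pos:
        root_seq[i] = rng.choice(NUC_STATES)
    invariant = {i for i in unpaired_pos if rng.random() < cfg.p_inv}

    partner = [None] * length
    for (i, j) in pairs:
        partner[i], partner[j] = j, i
    root_pt = PairTable(partner)
    root_ss = StructuredSequence(SequenceRecord("root", "".join(root_seq)), root_pt)

    # per-state jump rates for the two kernels
    dQ = dmodel.Q * cfg.paired_rate
    uQ = umodel.Q * cfg.unpaired_rate
    events = []

    def evolve_branch(seq, branch_name, t):
        seq = list(seq)
        deleted = set()
        for (i, j) in pairs:
            d = seq[i] + seq[j]
            time = 0.0
            while True:
                di = DOUBLET_STATES.index(d)
                rate = -dQ[di, di]
                if rate <= 0:
                    break
                time += rng.expovariate(rate)
                if time >= t:
                    break
                probs = np.clip(dQ[di], 0, None)
                probs[di] = 0.0
                probs = probs / probs.sum()
                new = rng.choices(DOUBLET_STATES, weights=probs)[0]
                preserving = d in VALID_PAIRS and new in VALID_PAIRS
                events.append({"branch": branch_name, "site_i": i, "site_j": j,
                               "from": d, "to": new,
                               "pairing_preserving": bool(preserving)})
                d = new
            seq[i], seq[j] = d[0], d[1]
        for i in unpaired_pos:
            if i in invariant:
                continue
            a = seq[i]
            time = 0.0
            while True:
                ai = NUC_STATES.index(a)
                rate = -uQ[ai, ai]
                if rate <= 0:
                    break
                time += rng.expovariate(rate)
                if time >= t:
                    break
                probs = np.clip(uQ[ai], 0, None)
                probs[ai] = 0.0
                probs = probs / probs.sum()
                new = rng.choices(NUC_STATES, weights=probs)[0]
                events.append({"branch": branch_name, "site_i": i, "site_j": -1,
                               "from": a, "to": new, "pairing_preserving": False})
                a = new
            seq[i] = a
        if cfg.indel_rate > 0:
            for i in unpaired_pos:
                if rng.random() < 1.0 - math.exp(-cfg.indel_rate * t):
                    deleted.add(i)
                    events.append({"branch": branch_name, "site_i": i, "site_j": -1,
                                   "from": seq[i], "to": "-",
                                   "pairing_preserving": False})
        return seq, deleted

    seqs = {}
    deletions = {}
    counter = [0]

    def name_of(node):
        if node.taxon is not None:
            return node.taxon.label
        if not hasattr(node, "_sim_name"):
            counter[0] += 1
            node._sim_name = f"N{counter[0]}"
        return node._sim_name

    seqs[id(tree.seed_node)] = list(root_seq)
    deletions[id(tree.seed_node)] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        s, dels = evolve_branch(parent_seq, name_of(node), node.edge.length or 0.0)
        seqs[id(node)] = s
        deletions[id(node)] = deletions[id(node.parent_node)] | dels

    rows = []
    leaf_records = []
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        s = seqs[id(leaf)]
        dels = deletions[id(leaf)]
        gapped = "".join("-" if i in dels else c for i, c in enumerate(s))
        struct = root_pt.to_dotbracket()
        rows.append(AlignedRow(lab, gapped, struct))
        leaf_records.append(SequenceRecord(lab, gapped.replace("-", "") or "A"))
    rows.sort(key=lambda r: r.id)
    leaf_records.sort(key=lambda r: r.id)
    aln = StructuralAlignment(rows, consensus_db=root_pt.to_dotbracket())
    truth = SimulationTruth(
        tree=tree,
        root=root_ss,
        alignment=aln,
        pairing_mask=sorted(pairs),
        event_log=pd.DataFrame(
            events, columns=["branch", "site_i", "site_j", "from", "to",
                             "pairing_preserving"]
        ),
    )
    return leaf_records, aln, truth


# ---------------------------------------------------------------------------
# Hand-built ITS2 toy with injectable hallmarks
# ---------------------------------------------------------------------------

def _helix(arm5: str, loop: str, mismatches=()):
    """Build (sequence, dotbracket) for one hairpin.

    ``mismatches`` lists (position within arm5, base_on_3prime) creating a
    1x1 internal loop instead of a pair at that stem position.
    """
    mm = dict(mismatches)
    arm3 = []
    db5, db3 = [], []
    for k, c in enumerate(arm5):
        if k in mm:
            arm3.append(mm[k])
            db5.append(".")
            db3.append(".")
        else:
            arm3.append(_COMPLEMENT[c])
            db5.append("(")
            db3.append(")")
    seq = arm5 + loop + "".join(reversed(arm3))
    db = "".join(db5) + "." * len(loop) + "".join(reversed(db3))
    return seq, db


def make_its2_toy(motif: bool = True, uu: bool = True, hybrid: bool = True,
                  seed: int = 0):
    """A four-helix toy ITS2 with each hallmark independently injectable.

    Returns ``(StructuredSequence, flank_5_8S, flank_28S)``.  Helix 2
    carries a 1x1 U-U internal loop (or U-C when ``uu`` is off); helix 3
    carries the conserved motif UGGU on its 5' arm near the apex (mutated
    to UCCU when ``motif`` is off); the flanks can form a 6-pair hybrid
    stem (broken when ``hybrid`` is off).  Stems are GC-rich and linkers
    are A-runs so the designed structure is also the thermodynamic optimum.
    """
    rng = random.Random(seed)
    spacers = ["A" * rng.randint(3, 5) for _ in range(4)]
    tail = "A" * rng.randint(2, 4)

    h1_seq, h1_db = _helix("GCGGC", "AAAA")
    h2_arm = "GCGGUCGG"
    h2_seq, h2_db = _helix(h2_arm, "AAAA", mismatches=[(4, "U" if uu else "C")])
    h3_arm5 = "GCGC" + ("UGGU" if motif else "UCCU") + "GC"
    h3_seq, h3_db = _helix(h3_arm5, "AAAA")
    h4_seq, h4_db = _helix("GGCGC", "AAAA")

    seq = (spacers[0] + h1_seq + spacers[1] + h2_seq + spacers[2] + h3_seq
           + spacers[3] + h4_seq + tail)
    db = ("." * len(spacers[0]) + h1_db + "." * len(spacers[1]) + h2_db
          + "." * len(spacers[2]) + h3_db + "." * len(spacers[3]) + h4_db
          + "." * len(tail))
    ss = StructuredSequence(
        SequenceRecord(f"its2_toy_{seed}", seq), PairTable.from_dotbracket(db)
    )
    f58 = "AAAG" + "ACCUGC"            # 3' end pairs the 28S 5' start
    f28 = "GCAGGU" if hybrid else "GCAUGU"
    f28 += "GAAA"
    return ss, f58, f28
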