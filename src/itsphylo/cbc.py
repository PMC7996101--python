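"""Compensatory (CBC) and hemi-compensatory (hCBC) base-change detection.

At a conserved base pair, two sequences may differ in zero, one or both
pairing partners.  If both partners differ and both doublets still form a
canonical pair (AU, UA, GC, CG, GU, UG) the change is a CBC; if exactly one
partner differs and pairing is retained it is an hCBC (the G-C <-> G-U
wobble exchange being the classic case).  A change that destroys pairing is
``pairing_lost``; doublets touching a gap or an ambiguity code are excluded
from the census (``other``).

Counting is site-level: a consensus pair is one hCBC (or CBC) site no
matter how many sequence pairs exhibit the change there.  Event-level
counts are also reported for transparency.  Changes are evaluated pairwise
between rows, not against a reconstructed ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .folding import VALID_PAIRS

__all__ = [
    "classify_doublet_change",
    "scan_alignment",
    "cbc_matrix",
    "PairChange",
    "CBCReport",
]

_CONCRETE = set("ACGU")


@dataclass
class PairChange:
    columns: tuple       # (i, j) alignment columns of the consensus pair
    rows: tuple          # (id_r, id_s)
    doublet_r: str
    doublet_s: str
    category: str


@dataclass
class CBCReport:
    n_cbc_sites: int
    n_hcbc_sites: int
    site_table: pd.DataFrame      # one record per (site, category) with members
    changes: list = field(default_factory=list)   # all PairChange records
    taxa: list = field(default_factory=list)
    n_cbc_events: int = 0
    n_hcbc_events: int = 0

    def sites(self, category: str) -> list:
        sub = self.site_table[self.site_table.category == category]
        return sorted(set(zip(sub.col_i, sub.col_j)))


def classify_doublet_change(d1: str, d2: str) -> str:
    """Classify the change between two ordered doublets.

    Returns one of ``identical``, ``CBC``, ``hCBC``, ``pairing_lost`` or
    ``other``.  Symmetric in its arguments (``pairing_lost`` is normalised
    to "lost relative to the valid doublet").  Any gap or ambiguity residue
    yields ``other`` and is excluded from counting.
    """
    d1, d2 = d1.upper().replace("T", "U"), d2.upper().replace("T", "U")
    if len(d1) != 2 or len(d2) != 2:
        raise ValueError("doublets must have length 2")
    if any(c not in _CONCRETE for c in d1 + d2):
        return "other"
    if d1 == d2:
        return "identical"
    v1, v2 = d1 in VALID_PAIRS, d2 in VALID_PAIRS
    ndiff = (d1[0] != d2[0]) + (d1[1] != d2[1])
    if v1 and v2:
        return "CBC" if ndiff == 2 else "hCBC"
    if v1 != v2:
        return "pairing_lost"
    return "other"


def scan_alignment(aln, consensus) -> CBCReport:
    """Census of base-pair changes over every consensus pair and row pair.

    A consensus pair is an hCBC (CBC) site if at least one unordered row
    pair classifies as hCBC (CBC) there.  The site table lists, per site
    and category, the contributing sequence pairs.
    """
    width = aln.width
    for i, j in consensus.pairs():
        if not (0 <= i < width and 0 <= j < width):
            raise ValueError(f"consensus pair ({i}, {j}) outside alignment width {width}")
    taxa = aln.ids()
    changes: list[PairChange] = []
    site_records = []
    n_cbc_sites = n_hcbc_sites = 0
    n_cbc_events = n_hcbc_events = 0
    for i, j in consensus.pairs():
        cats_here: dict[str, list] = {}
        for r, s in combinations(range(len(taxa)), 2):
            d_r = aln.rows[r].seq[i] + aln.rows[r].seq[j]
            d_s = aln.rows[s].seq[i] + aln.rows[s].seq[j]
            cat = classify_doublet_change(d_r, d_s)
            if cat in ("identical", "other"):
                continue
            changes.append(PairChange((i, j), (taxa[r], taxa[s]), d_r, d_s, cat))
            cats_here.setdefault(cat, []).append((taxa[r], taxa[s]))
            if cat == "CBC":
                n_cbc_events += 1
            elif cat == "hCBC":
                n_hcbc_events += 1
        if "CBC" in cats_here:
            n_cbc_sites += 1
        if "hCBC" in cats_here:
            n_hcbc_sites += 1
        for cat, members in sorted(cats_here.items()):
            site_records.append(
                {
                    "col_i": i,
                    "col_j": j,
                    "category": cat,
                    "n_pairs": len(members),
                    "members": ";".join(f"{a}|{b}" for a, b in members),
                }
            )
    table = pd.DataFrame(
        site_records, columns=["col_i", "col_j", "category", "n_pairs", "members"]
    )
    return CBCReport(
        n_cbc_sites=n_cbc_sites,
        n_hcbc_sites=n_hcbc_sites,
        site_table=table,
        changes=changes,
        taxa=list(taxa),
        n_cbc_events=n_cbc_events,
        n_hcbc_events=n_hcbc_events,
    )


def cbc_matrix(report: CBCReport, level: str = "CBC") -> pd.DataFrame:
    """Taxa x taxa matrix of per-pair site counts for CBC or hCBC.

    Entry (r, s) is the number of consensus pairs at which rows r and s
    show the given change; symmetric with a zero diagonal.
    """
    if level not in ("CBC", "hCBC"):
        raise ValueError(f"unknown level {level!r}; expected 'CBC' or 'hCBC'")
    taxa = report.taxa
    idx = {t: k for k, t in enumerate(taxa)}
    mat = np.zeros((len(taxa), len(taxa)), dtype=int)
    for ch in report.changes:
        if ch.category != level:
            continue
        a, b = idx[ch.rows[0]], idx[ch.rows[1]]
        mat[a, b] += 1
        mat[b, a] += 1
    return pd.DataFrame(mat, index=taxa, columns=taxa)
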