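"""Minimum-free-energy secondary-structure prediction for ITS-like RNAs.

A Zuker-style dynamic programme over nested structures with a reduced
nearest-neighbour model: stacking energies for the six canonical pairs
(AU, UA, GC, CG, GU, UG), tabulated hairpin/bulge/internal-loop penalties
with logarithmic extrapolation beyond length 30, and an affine multiloop
term.  No dangles, no coaxial stacking; 37 degrees C.  The table ships with
the package so every prediction is deterministic and self-contained.

``energy`` scores any given structure by full loop decomposition and is the
single source of truth: ``fold_mfe`` minimises exactly this function over
all nested structures (interior loops capped at ``max_interior`` unpaired
bases, which only binds for sequences longer than the cap).

``nussinov_maxpairs`` is the classic pair-count maximiser, kept as an
independent combinatorial baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core_io import PairTable, SequenceRecord, StructuredSequence

__all__ = [
    "VALID_PAIRS",
    "EnergyModel",
    "FoldResult",
    "default_energy_model",
    "energy",
    "fold_mfe",
    "nussinov_maxpairs",
    "is_valid_pair",
]

INF = float("inf")

#: Canonical pairs, Watson-Crick plus GU wobble.
VALID_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

# Stacking free energies in kcal/mol for 5'-ab-3' paired with 3'-xy-5':
# key ((a, b), (c, d)) where (a, b) is the outer pair (i, j) and (c, d) the
# inner pair (i+1, j-1).  Values follow the familiar nearest-neighbour
# ordering (GC/CG stacks strongest, wobble stacks weakest); the reciprocity
# identity E[(p, q)] = E[(reverse(q), reverse(p))] fills the remainder.
_STACK_BASE = {
    ("A", "U"): {"AU": -0.9, "UA": -1.1, "GC": -2.1, "CG": -2.2, "GU": -0.6, "UG": -1.4},
    ("U", "A"): {"AU": -1.3, "UA": -0.9, "GC": -2.1, "CG": -2.4, "GU": -1.0, "UG": -1.3},
    ("C", "G"): {"AU": -2.1, "UA": -2.1, "GC": -2.4, "CG": -3.3, "GU": -1.4, "UG": -2.1},
    ("G", "C"): {"AU": -2.4, "UA": -2.2, "GC": -3.3, "CG": -3.4, "GU": -1.5, "UG": -2.5},
    ("G", "U"): {"AU": -1.3, "UA": -1.4, "GC": -2.1, "CG": -2.5, "GU": -0.5, "UG": -0.6},
    ("U", "G"): {"AU": -1.0, "UA": -0.6, "GC": -1.4, "CG": -1.5, "GU": -0.3, "UG": -0.5},
}

# Loop initiation penalties (kcal/mol), indexed by number of unpaired bases.
# Hairpins of 1-2 nt are sterically strained: steep but finite, so that
# energy() can score any structure a parser accepts (folding itself never
# proposes them at the default min_loop of 3).
_HAIRPIN_TAB = {1: 9.0, 2: 7.0, 3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 4.1, 3: 4.5, 4: 4.9, 5: 5.3, 6: 5.7}

# 1.75 * R * T at 310 K, the standard Jacobson-Stockmayer prefactor.
_LOG_EXTRAP = 1.75 * 0.0019872 * 310.15


def _tabulated(tab: dict[int, float], n: int) -> float:
    if n <= 0:
        return INF
    if n in tab:
        return tab[n]
    m = max(tab)
    if n < min(tab):
        return INF
    return tab[m] + _LOG_EXTRAP * math.log(n / m)


@dataclass(frozen=True)
class EnergyModel:
    """Reduced nearest-neighbour parameter set (kcal/mol, 37 C)."""

    stack: dict = field(default_factory=dict)
    hairpin_tab: dict = field(default_factory=lambda: dict(_HAIRPIN_TAB))
    bulge_tab: dict = field(default_factory=lambda: dict(_BULGE_TAB))
    internal_tab: dict = field(default_factory=lambda: dict(_INTERNAL_TAB))
    multi_close: float = 3.4   # multiloop initiation (a)
    multi_branch: float = 0.4  # per branch, incl. the closing pair (b)
    multi_unpaired: float = 0.1  # per unpaired base in the multiloop (c)
    min_loop: int = 3
    max_interior: int = 30

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stack[(outer, inner)]

    def hairpin_penalty(self, n: int) -> float:
        return _tabulated(self.hairpin_tab, n)

    def bulge_penalty(self, n: int) -> float:
        return _tabulated(self.bulge_tab, n)

    def internal_penalty(self, n: int) -> float:
        return _tabulated(self.internal_tab, n)


def _full_stack_table() -> dict:
    """Expand the base table with the reciprocity identity."""
    full: dict = {}
    for (a, b), row in _STACK_BASE.items():
        for inner, e in row.items():
            full[(a + b, inner)] = e
    for outer in sorted(VALID_PAIRS):
        for inner in sorted(VALID_PAIRS):
            if (outer, inner) not in full:
                # view the stack from the opposite strand
                full[(outer, inner)] = full[(inner[::-1], outer[::-1])]
    return full


_DEFAULT_MODEL = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel(stack=_full_stack_table())
    return _DEFAULT_MODEL


def is_valid_pair(a: str, b: str) -> bool:
    """True iff (a, b) is a canonical pair; ambiguity codes never pair."""
    return a + b in VALID_PAIRS


@dataclass
class FoldResult:
    structure: PairTable
    delta_g: float
    alternates: list = field(default_factory=list)  # [(PairTable, dg), ...]


# ---------------------------------------------------------------------------
# Structure scoring by loop decomposition
# ---------------------------------------------------------------------------

def _children_of(pairs, i, j):
    """Directly enclosed pairs of (i, j), scanning left to right."""
    out = []
    k = i + 1
    bypartner = {}
    for a, b in pairs:
        bypartner[a] = b
    while k < j:
        if k in bypartner and bypartner[k] > k:
            out.append((k, bypartner[k]))
            k = bypartner[k] + 1
        else:
            k += 1
    return out


def energy(seq, structure: PairTable, model: EnergyModel | None = None) -> float:
    """Free energy of ``structure`` on ``seq`` by loop decomposition.

    Hairpins, bulges and internal loops take their tabulated penalties;
    adjacent pairs take stacking energies; multiloops take the affine
    ``a + b * (branches + 1) + c * unpaired`` term.  Exterior bases are
    free.  The empty structure scores 0 and the total is additive over
    independent substructures.
    """
    if model is None:
        model = default_energy_model()
    s = seq.residues if isinstance(seq, (SequenceRecord,)) else str(seq).upper().replace("T", "U")
    pairs = structure.pairs()
    for i, j in pairs:
        if not is_valid_pair(s[i], s[j]):
            raise ValueError(f"invalid pair doublet {s[i]}{s[j]} at ({i}, {j})")
    total = 0.0
    for i, j in pairs:
        children = _children_of(pairs, i, j)
        if not children:
            total += model.hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                total += model.stack_energy(s[i] + s[j], s[k] + s[l])
            elif left == 0 or right == 0:
                total += model.bulge_penalty(left + right)
            else:
                total += model.internal_penalty(left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += (
                model.multi_close
                + model.multi_branch * (len(children) + 1)
                + model.multi_unpaired * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# MFE folding (Zuker-style DP)
# ---------------------------------------------------------------------------

def fold_mfe(
    seq,
    model: EnergyModel | None = None,
    forced_pairs=None,
    forbidden_pairs=None,
    band_percent: float | None = None,
) -> FoldResult:
    """Fold ``seq`` to its minimum-free-energy nested structure.

    ``forced_pairs`` must appear in the result; ``forbidden_pairs`` may not.
    Contradictory constraints (a pair both forced and forbidden, a forced
    pair whose doublet cannot pair, or crossing forced pairs) raise
    ``ValueError``.  With ``band_percent`` set, deterministic alternates
    within that percentage of \\|MFE\\| are enumerated by refolding with
    each MFE pair forbidden in turn.

    Tie-breaking in the traceback is lexicographic in the DP case order and
    in (i, j), so output is reproducible for a fixed input.
    """
    if model is None:
        model = default_energy_model()
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", str(seq))
    s = rec.residues
    n = len(s)
    forced = {tuple(sorted(p)) for p in (forced_pairs or [])}
    forbidden = {tuple(sorted(p)) for p in (forbidden_pairs or [])}
    if forced & forbidden:
        clash = sorted(forced & forbidden)[0]
        raise ValueError(f"contradictory constraints: pair {clash} both forced and forbidden")
    for i, j in sorted(forced):
        if not is_valid_pair(s[i], s[j]):
            raise ValueError(f"forced pair ({i}, {j}) has invalid doublet {s[i]}{s[j]}")
        if j - i < model.min_loop + 1:
            raise ValueError(f"forced pair ({i}, {j}) violates min_loop={model.min_loop}")
    flist = sorted(forced)
    for a in range(len(flist)):
        for b in range(a + 1, len(flist)):
            (i, j), (k, l) = flist[a], flist[b]
            if i < k < j < l or i == k or j == l or i == l or j == k:
                raise ValueError(f"forced pairs {flist[a]} and {flist[b]} conflict")

    # forced pairs get a large bonus so any feasible optimum contains them;
    # positions taken by a forced pair may not pair elsewhere.
    BONUS = -1e6
    forced_pos = {p for pr in forced for p in pr}

    pt, _raw = _zuker(s, model, forced, forced_pos, forbidden, BONUS)
    for p in forced:
        if tuple(sorted(p)) not in set(pt.pairs()):
            raise ValueError(f"forced pair {p} is infeasible under the remaining constraints")
    dg = energy(s, pt, model)
    result = FoldResult(pt, dg)

    if band_percent is not None and pt.n_pairs() > 0:
        band = abs(dg) * band_percent / 100.0
        seen = {pt.to_dotbracket()}
        alts = []
        for p in pt.pairs():
            pt2, _ = _zuker(s, model, forced, forced_pos, forbidden | {p}, BONUS)
            ok = all(tuple(sorted(q)) in set(pt2.pairs()) for q in forced)
            if not ok:
                continue
            db = pt2.to_dotbracket()
            if db in seen:
                continue
            seen.add(db)
            dg2 = energy(s, pt2, model)
            if dg2 <= dg + band:
                alts.append((pt2, dg2))
        alts.sort(key=lambda t: (t[1], t[0].to_dotbracket()))
        result.alternates = alts
    return result


def _zuker(s, model, forced, forced_pos, forbidden, bonus):
    n = len(s)
    ml = model.min_loop
    maxint = model.max_interior

    def pairable(i, j):
        if (i, j) in forbidden:
            return False
        if i in forced_pos and (i, j) not in forced:
            return False
        if j in forced_pos and (i, j) not in forced:
            return False
        return is_valid_pair(s[i], s[j])

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]

    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V(i, j): energy given i pairs j -------------------------
            if pairable(i, j):
                best = model.hairpin_penalty(j - i - 1)
                # stack / bulge / internal via inner pair (k, l)
                for k in range(i + 1, min(j - 1, i + maxint + 2)):
                    left = k - i - 1
                    if left > maxint:
                        break
                    lmin = max(k + ml + 1, j - 1 - (maxint - left))
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k][l] == INF:
                            continue
                        right = j - l - 1
                        if left == 0 and right == 0:
                            loop_e = model.stack_energy(s[i] + s[j], s[k] + s[l])
                        elif left == 0 or right == 0:
                            loop_e = model.bulge_penalty(left + right)
                        else:
                            loop_e = model.internal_penalty(left + right)
                        cand = V[k][l] + loop_e
                        if cand < best:
                            best = cand
                # multiloop closure: two or more branches inside
                close = model.multi_close + model.multi_branch
                for k in range(i + 1, j - 1):
                    if WM[i + 1][k] < INF and WM[k + 1][j - 1] < INF:
                        cand = close + WM[i + 1][k] + WM[k + 1][j - 1]
                        if cand < best:
                            best = cand
                if (i, j) in forced:
                    best += bonus
                V[i][j] = best
            # --- WM(i, j): >=1 branch inside a multiloop -----------------
            best = INF
            if WM[i + 1][j] != INF:
                best = WM[i + 1][j] + model.multi_unpaired
            if WM[i][j - 1] != INF:
                best = min(best, WM[i][j - 1] + model.multi_unpaired)
            if V[i][j] != INF:
                best = min(best, V[i][j] + model.multi_branch)
            for k in range(i + 1, j):
                if WM[i][k - 1] != INF and WM[k][j] != INF:
                    cand = WM[i][k - 1] + WM[k][j]
                    if cand < best:
                        best = cand
            WM[i][j] = best

    # exterior loop
    W = [0.0] * (n + 1)  # W[j] = best over prefix s[0:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - ml - 1):
            if V[i][j - 1] != INF:
                cand = W[i] + V[i][j - 1]
                if cand < best:
                    best = cand
        W[j] = best

    # traceback (case order fixed -> deterministic)
    partner: list[int | None] = [None] * n
    eps = 1e-9

    def trace_v(i, j):
        partner[i], partner[j] = j, i
        target = V[i][j]
        if (i, j) in forced:
            target -= bonus
        if abs(target - model.hairpin_penalty(j - i - 1)) < eps:
            return
        for k in range(i + 1, min(j - 1, i + maxint + 2)):
            left = k - i - 1
            if left > maxint:
                break
            lmin = max(k + ml + 1, j - 1 - (maxint - left))
            for l in range(j - 1, lmin - 1, -1):
                if V[k][l] == INF:
                    continue
                right = j - l - 1
                if left == 0 and right == 0:
                    loop_e = model.stack_energy(s[i] + s[j], s[k] + s[l])
                elif left == 0 or right == 0:
                    loop_e = model.bulge_penalty(left + right)
                else:
                    loop_e = model.internal_penalty(left + right)
                if abs(target - (V[k][l] + loop_e)) < eps:
                    trace_v(k, l)
                    return
        close = model.multi_close + model.multi_branch
        for k in range(i + 1, j - 1):
            if WM[i + 1][k] < INF and WM[k + 1][j - 1] < INF:
                if abs(target - (close + WM[i + 1][k] + WM[k + 1][j - 1])) < eps:
                    trace_wm(i + 1, k)
                    trace_wm(k + 1, j - 1)
                    return
        raise AssertionError("traceback failed in V")

    def trace_wm(i, j):
        target = WM[i][j]
        if WM[i + 1][j] != INF and abs(target - (WM[i + 1][j] + model.multi_unpaired)) < eps:
            trace_wm(i + 1, j)
            return
        if WM[i][j - 1] != INF and abs(target - (WM[i][j - 1] + model.multi_unpaired)) < eps:
            trace_wm(i, j - 1)
            return
        if V[i][j] != INF and abs(target - (V[i][j] + model.multi_branch)) < eps:
            trace_v(i, j)
            return
        for k in range(i + 1, j):
            if WM[i][k - 1] != INF and WM[k][j] != INF:
                if abs(target - (WM[i][k - 1] + WM[k][j])) < eps:
                    trace_wm(i, k - 1)
                    trace_wm(k, j)
                    return
        raise AssertionError("traceback failed in WM")

    def trace_w(j):
        while j >= 1:
            if abs(W[j] - W[j - 1]) < eps and not _must_pair(j - 1):
                j -= 1
                continue
            done = False
            for i in range(0, j - ml - 1):
                if V[i][j - 1] != INF and abs(W[j] - (W[i] + V[i][j - 1])) < eps:
                    trace_v(i, j - 1)
                    j = i
                    done = True
                    break
            if not done:
                j -= 1

    def _must_pair(pos):
        return pos in forced_pos

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        trace_w(n)
    finally:
        sys.setrecursionlimit(old)
    return PairTable(partner, min_loop=0), W[n]


# ---------------------------------------------------------------------------
# Nussinov pair-count maximisation
# ---------------------------------------------------------------------------

def nussinov_maxpairs(seq, min_loop: int = 3) -> PairTable:
    """Maximise the number of canonical pairs over nested structures.

    Ties are broken deterministically: when pairing achieves the maximum,
    position ``i`` is paired with the smallest admissible ``k`` (smallest
    opening index first, then smallest span).
    """
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", str(seq))
    s = rec.residues
    n = len(s)
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if is_valid_pair(s[i], s[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 < j else 0
                    best = max(best, 1 + inner + right)
            N[i][j] = best

    partner: list[int | None] = [None] * n

    def trace(i, j):
        while i < j:
            if N[i][j] == 0:
                return
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if is_valid_pair(s[i], s[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 < j else 0
                    if 1 + inner + right == N[i][j]:
                        partner[i], partner[k] = k, i
                        trace(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        if n > 0:
            trace(0, n - 1)
    finally:
        sys.setrecursionlimit(old)
    return PairTable(partner, min_loop=0)


def fold_to_structured(rec: SequenceRecord, model=None, band_percent=None) -> StructuredSequence:
    """Convenience: fold a record and wrap the MFE result."""
    res = fold_mfe(rec, model=model, band_percent=band_percent)
    return StructuredSequence(rec, res.structure, delta_g=res.delta_g)
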