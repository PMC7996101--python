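"""Tree inference: NJ, maximum parsimony, maximum likelihood and Bayesian
MCMC, each runnable with and without secondary-structure information.

Structure enters in two ways.  For NJ/MP/ML the alignment may be given in
the 12-letter sequence+structure alphabet, scored under a 12-state model.
For likelihood-based methods a :class:`PartitionedAlignment` splits columns
into paired-doublet sites, scored under a 16-state doublet model whose only
allowed transitions change one nucleotide of the doublet at a time (so a
compensatory change requires two successive events), and unpaired sites
scored under 4x4 GTR with a proportion of invariant sites; gamma rate
heterogeneity uses four discrete categories (mean-of-quantile rates).

Trees are ``dendropy.Tree`` objects; clade support lives on internal nodes
as ``node.support`` (bootstrap percent or posterior probability).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .core_io import AMBIGUITY_MAP

__all__ = [
    "NUC_STATES",
    "CODE12_STATES",
    "DOUBLET_STATES",
    "SubstitutionModel",
    "PartitionedAlignment",
    "ml_distance",
    "ml_distance_matrix",
    "nj_tree",
    "parsimony_score",
    "mp_search",
    "likelihood",
    "ml_search",
    "bootstrap",
    "bayes_mcmc",
    "BayesResult",
    "tree_splits",
    "rf_distance",
    "random_topology",
    "leaf_labels",
]

NUC_STATES = "ACGU"
CODE12_STATES = "ABCDEFGHIJKL"
DOUBLET_STATES = tuple(a + b for a in NUC_STATES for b in NUC_STATES)


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-quantile discretisation of Gamma(alpha, mean 1) into k rates."""
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # mean of X over [a, b] for X ~ Gamma(alpha, 1/alpha):
    # k * (F_{alpha+1}(b) - F_{alpha+1}(a)) with F the CDF at shape alpha+1
    upper = gamma_dist.cdf(edges[1:], alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], alpha + 1, scale=1.0 / alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """A reversible CTMC on an arbitrary state alphabet, with +I and +G.

    Q is normalised to one expected substitution per unit time at
    stationarity; detailed balance (pi_i Q_ij = pi_j Q_ji) is enforced at
    construction.  Transition matrices come from the symmetrised
    eigendecomposition, cached on the model.
    """

    def __init__(self, states, Q, pi, p_inv: float = 0.0, gamma_alpha=None, n_cat: int = 4):
        self.states = tuple(states)
        self.k = len(self.states)
        Q = np.asarray(Q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if Q.shape != (self.k, self.k):
            raise ValueError(f"Q must be {self.k}x{self.k}")
        if not np.allclose(pi.sum(), 1.0):
            raise ValueError("stationary frequencies must sum to 1")
        if np.any(Q - np.diag(np.diag(Q)) < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("Q rows must sum to 0")
        flux = pi[:, None] * Q
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValueError("model is not reversible (detailed balance fails)")
        if not 0.0 <= p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        mu = -np.sum(pi * np.diag(Q))
        if mu <= 0:
            raise ValueError("Q has no substitution flux")
        self.Q = Q / mu
        self.pi = pi
        self.p_inv = float(p_inv)
        self.gamma_alpha = gamma_alpha
        self.n_cat = n_cat
        # symmetrised eigendecomposition (guard zero frequencies)
        sp = np.sqrt(np.maximum(pi, 1e-300))
        B = (self.Q * sp[:, None]) / sp[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = U / sp[:, None] * 1.0
        self._right = (U * sp[:, None]).T
        self._charmap_cache: dict[str, np.ndarray] = {}

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(P, 0.0, None)

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the variable-rate mixture, +I aware.

        The invariant category (rate 0, weight p_inv) is handled by the
        caller; variable rates are rescaled by 1/(1-p_inv) so the overall
        expected rate stays 1.
        """
        if self.gamma_alpha is None:
            rates = np.array([1.0])
        else:
            rates = _gamma_category_rates(self.gamma_alpha, self.n_cat)
        scale = 1.0 / (1.0 - self.p_inv) if self.p_inv > 0 else 1.0
        rates = rates * scale
        weights = np.full(len(rates), 1.0 / len(rates))
        return rates, weights

    # -- character handling -------------------------------------------------

    def char_vector(self, ch) -> np.ndarray:
        """0/1 vector of states compatible with an observed character."""
        key = ch
        if key in self._charmap_cache:
            return self._charmap_cache[key]
        vec = np.zeros(self.k)
        if self.k == 4:
            ch_ = str(ch).upper().replace("T", "U")
            if ch_ in ("-", "?", "."):
                vec[:] = 1.0
            else:
                for nuc in AMBIGUITY_MAP.get(ch_, "ACGU"):
                    vec[NUC_STATES.index(nuc)] = 1.0
        elif self.k == 12:
            if ch in CODE12_STATES:
                vec[CODE12_STATES.index(ch)] = 1.0
            else:  # '?', '-'
                vec[:] = 1.0
        elif self.k == 16:
            d = str(ch).upper().replace("T", "U")
            opts_a = AMBIGUITY_MAP.get(d[0], "ACGU") if d[0] in AMBIGUITY_MAP else "ACGU"
            opts_b = AMBIGUITY_MAP.get(d[1], "ACGU") if d[1] in AMBIGUITY_MAP else "ACGU"
            for a in opts_a:
                for b in opts_b:
                    vec[DOUBLET_STATES.index(a + b)] = 1.0
        else:
            raise ValueError(f"unsupported alphabet size {self.k}")
        self._charmap_cache[key] = vec
        return vec

    # -- factories ----------------------------------------------------------

    @classmethod
    def jc(cls, n_states: int = 4, p_inv: float = 0.0, gamma_alpha=None):
        """Equal-rates, equal-frequency model on 4, 12 or 16 states."""
        states = {4: NUC_STATES, 12: CODE12_STATES, 16: DOUBLET_STATES}[n_states]
        Q = np.full((n_states, n_states), 1.0)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        pi = np.full(n_states, 1.0 / n_states)
        return cls(states, Q, pi, p_inv=p_inv, gamma_alpha=gamma_alpha)

    @classmethod
    def gtr(cls, exch=None, pi=None, p_inv: float = 0.0, gamma_alpha=None):
        """General time-reversible 4-state model.

        ``exch`` orders the six exchangeabilities AC, AG, AU, CG, CU, GU.
        """
        if exch is None:
            exch = [1.0] * 6
        if pi is None:
            pi = [0.25] * 4
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        R = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), e in zip(pairs, exch):
            R[i, j] = R[j, i] = e
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(NUC_STATES, Q, pi, p_inv=p_inv, gamma_alpha=gamma_alpha)

    @classmethod
    def doublet(cls, pi=None, exch: float = 1.0, p_inv: float = 0.0, gamma_alpha=None):
        """16-state base-pair doublet model restricted to single-nucleotide
        transitions: rate(d -> d') = exch * pi_d' iff d and d' differ at
        exactly one position, else 0."""
        if pi is None:
            pi = np.full(16, 1e-4)
            valid = ["AU", "UA", "GC", "CG", "GU", "UG"]
            for d in valid:
                pi[DOUBLET_STATES.index(d)] = (1.0 - 10 * 1e-4) / 6
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = np.zeros((16, 16))
        for i, di in enumerate(DOUBLET_STATES):
            for j, dj in enumerate(DOUBLET_STATES):
                if i == j:
                    continue
                ndiff = (di[0] != dj[0]) + (di[1] != dj[1])
                if ndiff == 1:
                    Q[i, j] = exch * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(DOUBLET_STATES, Q, pi, p_inv=p_inv, gamma_alpha=gamma_alpha)

    @classmethod
    def gtr_from_alignment(cls, rows, p_inv: float = 0.0, gamma_alpha=None, pseudocount: float = 1.0):
        """Empirical GTR: frequencies and exchangeabilities by counting over
        all sequence pairs (a simple moment estimator; adequate as a default
        when no rate matrix is supplied)."""
        seqs = [s for _, s in rows]
        counts = np.full(4, pseudocount)
        pair_counts = np.full((4, 4), pseudocount)
        idx = {c: k for k, c in enumerate(NUC_STATES)}
        for s in seqs:
            for c in s:
                if c in idx:
                    counts[idx[c]] += 1
        for a in range(len(seqs)):
            for b in range(a + 1, len(seqs)):
                for ca, cb in zip(seqs[a], seqs[b]):
                    if ca in idx and cb in idx and ca != cb:
                        pair_counts[idx[ca], idx[cb]] += 1
                        pair_counts[idx[cb], idx[ca]] += 1
        pi = counts / counts.sum()
        exch = []
        for (i, j) in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            exch.append(pair_counts[i, j] / (pi[i] * pi[j]))
        exch = np.array(exch)
        exch = exch / exch[-1]  # GU-normalised
        return cls.gtr(exch=exch, pi=pi, p_inv=p_inv, gamma_alpha=gamma_alpha)


# ---------------------------------------------------------------------------
# Data containers and pattern compression
# ---------------------------------------------------------------------------

def _coerce_rows(data) -> list[tuple[str, str]]:
    """Accept a StructuralAlignment, a list of (id, string), or a dict."""
    if hasattr(data, "nucleotide_rows"):
        return data.nucleotide_rows()
    if isinstance(data, dict):
        return list(data.items())
    return [(rid, str(s)) for rid, s in data]


class PartitionedAlignment:
    """Alignment columns split into doublet (paired) and unpaired sites."""

    def __init__(self, taxa, doublet_sites, doublet_rows, unpaired_rows):
        self.taxa = list(taxa)
        self.doublet_sites = list(doublet_sites)
        self.doublet_rows = doublet_rows      # {taxon: [2-char str, ...]}
        self.unpaired_rows = unpaired_rows    # {taxon: str}
        nd = len(self.doublet_sites)
        for t in self.taxa:
            if len(self.doublet_rows[t]) != nd:
                raise ValueError(f"doublet row length mismatch for {t!r}")

    @classmethod
    def from_alignment(cls, aln, consensus) -> "PartitionedAlignment":
        """Split a StructuralAlignment by its consensus pairing mask."""
        pairs = sorted(consensus.pairs()) if hasattr(consensus, "pairs") else sorted(consensus)
        paired_cols = set()
        for i, j in pairs:
            if i in paired_cols or j in paired_cols:
                raise ValueError(f"column reused by consensus pair ({i}, {j})")
            paired_cols.update((i, j))
        if paired_cols and max(paired_cols) >= aln.width:
            raise ValueError("consensus pair beyond alignment width")
        unpaired_cols = [c for c in range(aln.width) if c not in paired_cols]
        drows, urows = {}, {}
        for row in aln.rows:
            drows[row.id] = [row.seq[i] + row.seq[j] for i, j in pairs]
            urows[row.id] = "".join(row.seq[c] for c in unpaired_cols)
        return cls(aln.ids(), pairs, drows, urows)

    def n_units(self) -> int:
        return len(self.doublet_sites) + len(next(iter(self.unpaired_rows.values())))

    def resample(self, rng) -> "PartitionedAlignment":
        """Bootstrap-resample doublet sites and unpaired columns as units."""
        nd = len(self.doublet_sites)
        nu = len(next(iter(self.unpaired_rows.values())))
        units = nd + nu
        draw = rng.integers(0, units, size=units)
        d_idx = [u for u in draw if u < nd]
        u_idx = [u - nd for u in draw if u >= nd]
        drows = {t: [self.doublet_rows[t][i] for i in d_idx] for t in self.taxa}
        urows = {t: "".join(self.unpaired_rows[t][i] for i in u_idx) for t in self.taxa}
        sites = [self.doublet_sites[i] for i in d_idx]
        return PartitionedAlignment(self.taxa, sites, drows, urows)

    def flat_nucleotide_rows(self) -> list[tuple[str, str]]:
        """Doublets expanded to two nucleotide columns + unpaired columns."""
        out = []
        for t in self.taxa:
            s = "".join(self.doublet_rows[t]) + self.unpaired_rows[t]
            out.append((t, s))
        return out


def _compress(rows: list[tuple[str, str]], tokens=None):
    """Site-pattern compression: returns (taxa, patterns, counts) where
    patterns is a list of per-taxon token tuples."""
    taxa = [rid for rid, _ in rows]
    if tokens is None:
        cols = list(zip(*[s for _, s in rows]))
    else:
        cols = list(zip(*[tokens[rid] for rid, _ in rows])) if isinstance(tokens, dict) else tokens
    pat: dict[tuple, int] = {}
    for col in cols:
        pat[col] = pat.get(col, 0) + 1
    patterns = list(pat.keys())
    counts = np.array([pat[p] for p in patterns], dtype=float)
    return taxa, patterns, counts


# ---------------------------------------------------------------------------
# Felsenstein pruning
# ---------------------------------------------------------------------------

def _leaf_partials(model, taxa, patterns):
    npat = len(patterns)
    out = {}
    for ti, t in enumerate(taxa):
        arr = np.empty((npat, model.k))
        for p, col in enumerate(patterns):
            arr[p] = model.char_vector(col[ti])
        out[t] = arr
    return out


def _site_likelihoods_rate(tree, model, partials, rate):
    cache = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cache[id(node)] = partials[node.taxon.label]
            continue
        prod = None
        for ch in node.child_nodes():
            t = (ch.edge.length or 0.0) * rate
            P = model.transition_matrix(t)
            term = cache[id(ch)] @ P.T
            prod = term if prod is None else prod * term
        cache[id(node)] = prod
    return cache[id(tree.seed_node)] @ model.pi


def _pattern_loglik(tree, model, taxa, patterns, counts, partials=None):
    if partials is None:
        partials = _leaf_partials(model, taxa, patterns)
    rates, weights = model.rate_categories()
    site_l = np.zeros(len(patterns))
    if model.p_inv > 0:
        const = np.ones((len(patterns), model.k))
        for t in taxa:
            const *= partials[t]
        site_l += model.p_inv * (const @ model.pi)
    var_w = 1.0 - model.p_inv
    for r, w in zip(rates, weights):
        site_l += var_w * w * _site_likelihoods_rate(tree, model, partials, r)
    with np.errstate(divide="ignore"):
        logs = np.log(site_l)
    if np.any(~np.isfinite(logs)):
        warnings.warn("site with zero likelihood (zero-frequency state observed)")
    return float(np.dot(counts, logs))


def likelihood(tree, data, model=None, unpaired_model=None, doublet_model=None) -> float:
    """Log-likelihood of ``data`` on ``tree`` by Felsenstein pruning.

    ``data`` is either plain rows (one ``model``) or a
    :class:`PartitionedAlignment`, in which case the doublet partition is
    scored under ``doublet_model`` (16-state) and the unpaired partition
    under ``unpaired_model`` (4-state GTR+I); the total is their sum.  An
    empty paired partition reduces exactly to the plain model likelihood.
    """
    if isinstance(data, PartitionedAlignment):
        if unpaired_model is None or doublet_model is None:
            raise ValueError("partitioned data needs unpaired_model and doublet_model")
        total = 0.0
        if data.doublet_sites:
            rows = [(t, None) for t in data.taxa]
            cols = list(zip(*[data.doublet_rows[t] for t in data.taxa]))
            taxa, patterns, counts = data.taxa, *_compress_cols(cols)
            total += _pattern_loglik(tree, doublet_model, taxa, patterns, counts)
        if len(next(iter(data.unpaired_rows.values()))) > 0:
            rows = [(t, data.unpaired_rows[t]) for t in data.taxa]
            taxa, patterns, counts = _compress(rows)
            total += _pattern_loglik(tree, unpaired_model, taxa, patterns, counts)
        return total
    if model is None:
        raise ValueError("plain data needs a model")
    rows = _coerce_rows(data)
    taxa, patterns, counts = _compress(rows)
    return _pattern_loglik(tree, model, taxa, patterns, counts)


def _compress_cols(cols):
    pat: dict[tuple, int] = {}
    for col in cols:
        pat[col] = pat.get(col, 0) + 1
    patterns = list(pat.keys())
    counts = np.array([pat[p] for p in patterns], dtype=float)
    return patterns, counts


class _Evaluator:
    """Cached likelihood evaluator: site patterns and leaf partials are
    compressed once, so repeated evaluations (branch optimisation, MCMC)
    only pay for the pruning pass."""

    def __init__(self, data, model=None, unpaired_model=None, doublet_model=None):
        self.parts = []  # [(model, taxa, patterns, counts, partials)]
        if isinstance(data, PartitionedAlignment):
            if unpaired_model is None or doublet_model is None:
                raise ValueError("partitioned data needs unpaired_model and doublet_model")
            if data.doublet_sites:
                cols = list(zip(*[data.doublet_rows[t] for t in data.taxa]))
                patterns, counts = _compress_cols(cols)
                partials = _leaf_partials(doublet_model, data.taxa, patterns)
                self.parts.append([doublet_model, data.taxa, patterns, counts, partials])
            if len(next(iter(data.unpaired_rows.values()))) > 0:
                rows = [(t, data.unpaired_rows[t]) for t in data.taxa]
                taxa, patterns, counts = _compress(rows)
                partials = _leaf_partials(unpaired_model, taxa, patterns)
                self.parts.append([unpaired_model, taxa, patterns, counts, partials])
        else:
            if model is None:
                raise ValueError("plain data needs a model")
            rows = _coerce_rows(data)
            taxa, patterns, counts = _compress(rows)
            partials = _leaf_partials(model, taxa, patterns)
            self.parts.append([model, taxa, patterns, counts, partials])

    def loglik(self, tree) -> float:
        return sum(
            _pattern_loglik(tree, m, taxa, patterns, counts, partials)
            for m, taxa, patterns, counts, partials in self.parts
        )

    def with_pinv(self, part_index: int, p: float) -> "_Evaluator":
        """Shallow copy with one partition's p_inv replaced (shares partials)."""
        ev = _Evaluator.__new__(_Evaluator)
        ev.parts = [list(p_) for p_ in self.parts]
        ev.parts[part_index][0] = _with_pinv(self.parts[part_index][0], p)
        return ev


# ---------------------------------------------------------------------------
# ML distances
# ---------------------------------------------------------------------------

def ml_distance(seq_a, seq_b, model, max_distance: float = 5.0, ids=("a", "b")) -> float:
    """Pairwise ML distance under ``model`` (numeric 2-sequence optimum).

    Sites where either sequence is fully missing are dropped; an empty
    overlap raises.  Saturated pairs are capped at ``max_distance`` with a
    warning.  Identical sequences return exactly 0.
    """
    va, vb = [], []
    for ca, cb in zip(seq_a, seq_b):
        xa, xb = model.char_vector(ca), model.char_vector(cb)
        if xa.sum() == model.k or xb.sum() == model.k:
            continue
        va.append(xa)
        vb.append(xb)
    if not va:
        raise ValueError(f"empty overlap between sequences {ids[0]!r} and {ids[1]!r}")
    A = np.array(va)
    B = np.array(vb)
    if np.all((A * B).sum(axis=1) > 0) and np.all(A.argmax(axis=1) == B.argmax(axis=1)) and np.all(A.sum(axis=1) == 1):
        return 0.0
    rates, weights = model.rate_categories()
    piA = A * model.pi

    def nll(t):
        site = np.zeros(len(A))
        if model.p_inv > 0:
            site += model.p_inv * ((A * B) @ model.pi)
        varw = 1.0 - model.p_inv
        for r, w in zip(rates, weights):
            P = model.transition_matrix(t * r)
            site += varw * w * np.einsum("ij,jk,ik->i", piA, P, B)
        site = np.maximum(site, 1e-300)
        return -np.log(site).sum()

    def dnll(t):
        # analytic gradient via the eigendecomposition
        num = np.zeros(len(A))
        site = np.zeros(len(A))
        if model.p_inv > 0:
            site += model.p_inv * ((A * B) @ model.pi)
        varw = 1.0 - model.p_inv
        for r, w in zip(rates, weights):
            P = model.transition_matrix(t * r)
            dP = (model._left * (model._lam * np.exp(model._lam * t * r))) @ model._right
            site += varw * w * np.einsum("ij,jk,ik->i", piA, P, B)
            num += varw * w * r * np.einsum("ij,jk,ik->i", piA, dP, B)
        site = np.maximum(site, 1e-300)
        return -np.sum(num / site)

    res = minimize_scalar(nll, bounds=(1e-10, max_distance), method="bounded",
                          options={"xatol": 1e-12})
    t = float(res.x)
    # polish to near machine precision with the analytic gradient
    lo, hi = max(1e-10, t - 1e-3), min(max_distance, t + 1e-3)
    try:
        if dnll(lo) < 0 < dnll(hi):
            from scipy.optimize import brentq

            t = float(brentq(dnll, lo, hi, xtol=1e-14))
    except ValueError:
        pass
    if t > max_distance - 1e-3 or nll(max_distance) <= res.fun + 1e-10:
        warnings.warn(f"saturated pair ({ids[0]}, {ids[1]}): distance capped at {max_distance}")
        return max_distance
    if nll(1e-10) <= res.fun + 1e-12:
        return 0.0
    return t


def ml_distance_matrix(data, model, max_distance: float = 5.0):
    """All pairwise ML distances; returns (labels, numpy matrix)."""
    rows = _coerce_rows(data)
    labels = [rid for rid, _ in rows]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_distance(rows[i][1], rows[j][1], model, max_distance,
                            ids=(labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    return labels, D


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(D, labels) -> dendropy.Tree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved by the lexicographic order of the
    joined nodes' sorted leaf-label keys.  Negative branch lengths are
    clamped to 0 with the deficit moved to the sister branch.  Recovers any
    additive matrix exactly.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(list(labels))
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    keys = [(lab,) for lab in labels]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i, j):
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    store = {}
    for i in active:
        for j in active:
            if i < j:
                store[(i, j)] = D[i, j]
    dist = store
    node_of = {i: nodes[i] for i in active}
    key_of = {i: keys[i] for i in active}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                cand_key = tuple(sorted((key_of[i], key_of[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and cand_key < best[3]
                ):
                    best = (q, i, j, cand_key)
        _, i, j, _ = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = dendropy.Node()
        ni, nj_ = node_of[i], node_of[j]
        new.add_child(ni)
        ni.edge.length = li
        new.add_child(nj_)
        nj_.edge.length = lj
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = new
        key_of[u] = tuple(sorted(key_of[i] + key_of[j]))

    # final trichotomy by the three-point formulas
    i, j, k = active
    root = dendropy.Node()
    lens = {
        i: 0.5 * (d(i, j) + d(i, k) - d(j, k)),
        j: 0.5 * (d(i, j) + d(j, k) - d(i, k)),
        k: 0.5 * (d(i, k) + d(j, k) - d(i, j)),
    }
    for idx in (i, j, k):
        nd = node_of[idx]
        root.add_child(nd)
        nd.edge.length = max(lens[idx], 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for nd in tree.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None
    return tree


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def leaf_labels(tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def tree_splits(tree, supported_only=False, cutoff=None) -> dict:
    """Non-trivial splits as {frozenset(side without anchor): support}.

    The anchor is the lexicographically smallest leaf label, making split
    identity well-defined for unrooted comparison.
    """
    labels = leaf_labels(tree)
    anchor = labels[0]
    full = frozenset(labels)
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if anchor not in clade else full - clade
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        sup = getattr(node, "support", None)
        out[side] = sup
    return out


def rf_distance(tree_a, tree_b) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    sa = set(tree_splits(tree_a))
    sb = set(tree_splits(tree_b))
    return len(sa ^ sb)


def random_topology(labels, rng) -> dendropy.Tree:
    """Uniform random-addition unrooted topology, branch lengths 0.1."""
    labels = list(labels)
    rng.shuffle(labels)
    tns = dendropy.TaxonNamespace(sorted(labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    root = dendropy.Node()
    for nd in nodes[:3]:
        root.add_child(nd)
        nd.edge.length = 0.1
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for nd in nodes[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        e = edges[rng.randrange(len(edges))]
        head, tail = e.head_node, e.tail_node
        mid = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(mid)
        mid.edge.length = 0.05
        mid.add_child(head)
        head.edge.length = 0.05
        mid.add_child(nd)
        nd.edge.length = 0.1
    return tree


def _clone(tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def _internal_edges(tree):
    out = []
    for e in tree.preorder_edge_iter():
        if e.tail_node is None or e.head_node.is_leaf():
            continue
        out.append(e)
    return out


def nni_neighbors(tree):
    """All NNI rearrangements of a tree (deterministic order)."""
    n_int = len(_internal_edges(tree))
    for e_idx in range(n_int):
        for c_idx in range(2):
            base = _clone(tree)
            edges = _internal_edges(base)
            e = edges[e_idx]
            v, u = e.head_node, e.tail_node
            vkids = v.child_nodes()
            ukids = [c for c in u.child_nodes() if c is not v]
            if len(vkids) < 2 or not ukids:
                continue
            s = ukids[0]
            c = vkids[c_idx]
            u.remove_child(s)
            v.remove_child(c)
            u.add_child(c)
            v.add_child(s)
            yield base


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def _state_masks(alphabet: str):
    if alphabet in ("nuc", "4", NUC_STATES):
        order = NUC_STATES
        amb = {k: v for k, v in AMBIGUITY_MAP.items()}

        def mask(ch):
            ch = ch.upper().replace("T", "U")
            if ch in ("-", "?", "."):
                return (1 << 4) - 1
            bits = 0
            for nuc in amb.get(ch, order):
                bits |= 1 << order.index(nuc)
            return bits

        return mask, 4
    if alphabet in ("code12", "12", CODE12_STATES):
        order = CODE12_STATES

        def mask(ch):
            if ch in order:
                return 1 << order.index(ch)
            return (1 << 12) - 1

        return mask, 12
    raise ValueError(f"unknown alphabet {alphabet!r}")


def parsimony_score(tree, data, alphabet: str = "nuc") -> int:
    """Fitch parsimony score (minimum mutation count, unordered states).

    ``-`` and ``?`` are treated as missing (compatible with any state).
    """
    rows = _coerce_rows(data)
    mask_fn, _ = _state_masks(alphabet)
    seqs = {rid: np.array([mask_fn(c) for c in s], dtype=np.int64) for rid, s in rows}
    score = np.zeros(len(next(iter(seqs.values()))), dtype=np.int64)
    cache = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cache[id(node)] = seqs[node.taxon.label]
            continue
        kids = node.child_nodes()
        m = cache[id(kids[0])]
        for ch in kids[1:]:
            other = cache[id(ch)]
            inter = m & other
            union = m | other
            miss = inter == 0
            score += miss.astype(np.int64)
            m = np.where(miss, union, inter)
        cache[id(node)] = m
    return int(score.sum())


def mp_search(data, alphabet: str = "nuc", n_starts: int = 5, seed: int = 0):
    """Maximum parsimony by random stepwise addition + NNI hill climbing.

    Returns the list of all tied-best trees found (unique topologies),
    deterministic for a fixed seed.
    """
    rows = _coerce_rows(data)
    if len(rows) < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    rng = random.Random(seed)
    best_trees: list = []
    best_score = None
    for _ in range(n_starts):
        order = list(range(len(rows)))
        rng.shuffle(order)
        labels = [rows[i][0] for i in order]
        tree = _stepwise_addition(labels, rows, alphabet)
        tree, score = _nni_hillclimb_mp(tree, rows, alphabet)
        if best_score is None or score < best_score:
            best_score = score
            best_trees = [tree]
        elif score == best_score:
            splits = set(tree_splits(tree))
            if all(splits != set(tree_splits(t)) for t in best_trees):
                best_trees.append(tree)
    return best_trees, best_score


def _stepwise_addition(labels, rows, alphabet):
    data = dict(rows)
    tns = dendropy.TaxonNamespace(sorted(data))
    root = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for lab in labels[:3]:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        root.add_child(nd)
        nd.edge.length = 0.1
    sub = {lab: data[lab] for lab in labels[:3]}
    for lab in labels[3:]:
        sub[lab] = data[lab]
        best = None
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        for k in range(len(edges)):
            t2 = _clone(tree)
            e2 = [e for e in t2.preorder_edge_iter() if e.tail_node is not None][k]
            head, tail = e2.head_node, e2.tail_node
            mid = dendropy.Node()
            tail.remove_child(head)
            tail.add_child(mid)
            mid.edge.length = 0.05
            mid.add_child(head)
            head.edge.length = 0.05
            leafnd = dendropy.Node(taxon=t2.taxon_namespace.get_taxon(lab))
            mid.add_child(leafnd)
            leafnd.edge.length = 0.1
            sc = parsimony_score(t2, list(sub.items()), alphabet)
            if best is None or sc < best[0]:
                best = (sc, t2)
        tree = best[1]
    return tree


def _nni_hillclimb_mp(tree, rows, alphabet):
    score = parsimony_score(tree, rows, alphabet)
    improved = True
    while improved:
        improved = False
        for nb in nni_neighbors(tree):
            sc = parsimony_score(nb, rows, alphabet)
            if sc < score:
                tree, score = nb, sc
                improved = True
                break
    return tree, score


# ---------------------------------------------------------------------------
# ML tree search
# ---------------------------------------------------------------------------

def _optimize_branch_lengths(tree, ev: _Evaluator, sweeps: int = 2,
                             max_len: float = 10.0):
    for _ in range(sweeps):
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue

            def nll(t):
                node.edge.length = t
                return -ev.loglik(tree)

            res = minimize_scalar(nll, bounds=(1e-8, max_len), method="bounded",
                                  options={"xatol": 1e-6})
            node.edge.length = float(res.x)
    return ev.loglik(tree)


def _distance_start_tree(data, model):
    if isinstance(data, PartitionedAlignment):
        rows = data.flat_nucleotide_rows()
        dmodel = SubstitutionModel.jc(4)
    else:
        rows = _coerce_rows(data)
        alpha_len = model.k if model is not None else 4
        dmodel = SubstitutionModel.jc(alpha_len)
    labels, D = ml_distance_matrix(rows, dmodel)
    return nj_tree(D, labels)


def ml_search(data, model=None, unpaired_model=None, doublet_model=None,
              seed: int = 0, tol: float = 1e-6, max_rounds: int = 20):
    """Maximum-likelihood tree: NJ start, alternating NNI moves and Brent
    branch-length optimisation until the improvement drops below ``tol``.

    Returns ``(tree, logL)``; deterministic for fixed inputs.
    """
    rows = data.taxa if isinstance(data, PartitionedAlignment) else [r for r, _ in _coerce_rows(data)]
    if len(rows) < 4:
        raise ValueError("ML search needs at least 4 taxa")
    ev = _Evaluator(data, model=model, unpaired_model=unpaired_model,
                    doublet_model=doublet_model)
    tree = _distance_start_tree(data, model)
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node and (nd.edge.length is None or nd.edge.length < 1e-6):
            nd.edge.length = 1e-6
    logl = _optimize_branch_lengths(tree, ev)
    for _ in range(max_rounds):
        best_nb, best_logl = None, logl
        for nb in nni_neighbors(tree):
            l_nb = _optimize_branch_lengths(nb, ev, sweeps=1)
            if l_nb > best_logl + tol:
                best_nb, best_logl = nb, l_nb
        if best_nb is None:
            break
        tree, logl = best_nb, best_logl
        logl = _optimize_branch_lengths(tree, ev)
    for nd in tree.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None
    return tree, logl


# ---------------------------------------------------------------------------
# Bootstrap + consensus
# ---------------------------------------------------------------------------

def _resample_rows(rows, rng):
    n = len(rows[0][1])
    idx = rng.integers(0, n, size=n)
    return [(rid, "".join(s[i] for i in idx)) for rid, s in rows]


def consensus_from_splits(split_freqs: dict, labels, cutoff: float,
                          scale: float = 100.0) -> dendropy.Tree:
    """Majority-rule consensus tree from split frequencies in [0, 1].

    Splits at or above ``cutoff`` are added greedily by decreasing
    frequency, skipping incompatible ones; supports are stored as
    ``freq * scale`` (percent for bootstrap, probability with scale 1).
    """
    labels = sorted(labels)
    anchor = labels[0]
    accepted: list[tuple[frozenset, float]] = []
    order = sorted(split_freqs.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    for side, f in order:
        if f < cutoff:
            continue
        ok = True
        for other, _ in accepted:
            if not (side <= other or other <= side or not (side & other)):
                ok = False
                break
        if ok:
            accepted.append((side, f))
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    tree.seed_node = root
    # nest clades by containment (anchor side excluded -> clades are rooted
    # at the anchor; the family is laminar by construction)
    accepted.sort(key=lambda t: -len(t[0]))
    clade_nodes: list[tuple[frozenset, dendropy.Node]] = []
    for side, f in accepted:
        # parent = smallest accepted clade strictly containing this one
        parent, best = root, None
        for cs, cn in clade_nodes:
            if side < cs and (best is None or len(cs) < best):
                parent, best = cn, len(cs)
        nd = dendropy.Node()
        nd.support = f * scale
        nd.edge.length = None
        parent.add_child(nd)
        clade_nodes.append((side, nd))
    for lab in labels:
        parent = root
        best_size = None
        for cs, cn in clade_nodes:
            if lab in cs and (best_size is None or len(cs) < best_size):
                parent = cn
                best_size = len(cs)
        leafnd = dendropy.Node(taxon=tns.get_taxon(lab))
        parent.add_child(leafnd)
    root.support = None
    return tree


def bootstrap(data, method: str, model=None, unpaired_model=None, doublet_model=None,
              alphabet: str = "nuc", n_reps: int = 1000, cutoff: float = 0.5,
              seed: int = 0) -> dendropy.Tree:
    """Nonparametric bootstrap with majority-rule consensus.

    Columns are resampled with replacement; for a
    :class:`PartitionedAlignment` a doublet site's two columns travel
    together as one unit.  ``method`` is ``nj``, ``mp`` or ``ml``.  Clade
    supports are percentages; clades below ``cutoff`` (a fraction) are
    collapsed.  Reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("nj", "mp", "ml"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    rng = np.random.default_rng(seed)
    partitioned = isinstance(data, PartitionedAlignment)
    labels = data.taxa if partitioned else [r for r, _ in _coerce_rows(data)]
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        if partitioned:
            rep = data.resample(rng)
        else:
            rep = _resample_rows(_coerce_rows(data), rng)
        if method == "nj":
            if partitioned:
                rows = rep.flat_nucleotide_rows()
                mdl = model or SubstitutionModel.jc(4)
            else:
                rows = rep
                mdl = model
            labs, D = ml_distance_matrix(rows, mdl)
            tree = nj_tree(D, labs)
        elif method == "mp":
            rows = rep.flat_nucleotide_rows() if partitioned else rep
            trees, _ = mp_search(rows, alphabet=alphabet, n_starts=1,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            tree = trees[0]
        else:
            tree, _ = ml_search(rep if partitioned else rep, model=model,
                                unpaired_model=unpaired_model,
                                doublet_model=doublet_model)
        for side in tree_splits(tree):
            counts[side] = counts.get(side, 0) + 1
    freqs = {side: c / n_reps for side, c in counts.items()}
    return consensus_from_splits(freqs, labels, cutoff=cutoff, scale=100.0)


# ---------------------------------------------------------------------------
# Bayesian MCMC
# ---------------------------------------------------------------------------

@dataclass
class BayesResult:
    consensus: dendropy.Tree
    split_posterior: dict
    asdsf: float
    converged: bool
    trace: pd.DataFrame
    samples: list = field(default_factory=list)   # per run: list of newick strings

    def supported_splits(self, cutoff: float = 0.95):
        return {s: p for s, p in self.split_posterior.items() if p > cutoff}


def bayes_mcmc(data, model=None, unpaired_model=None, doublet_model=None,
               n_iter: int = 100_000, sample_freq: int = 100, n_runs: int = 2,
               burnin_frac: float = 0.1, seed: int = 0,
               branch_prior_rate: float = 10.0) -> BayesResult:
    """Metropolis-Hastings sampler over topology, branch lengths and the
    invariant-site proportion.

    Proposals: NNI on a random internal edge, a multiplier move on a random
    branch length, and a sliding window on p_inv (when the model has one).
    Priors: exponential(``branch_prior_rate``) branch lengths, uniform
    topology, uniform p_inv.  ``n_runs`` independent runs are compared by
    the average standard deviation of split frequencies (ASDSF; splits at
    pooled frequency >= 0.1); convergence is declared below 0.01.  The
    consensus is the 50%-majority tree of pooled post-burnin samples with
    clade posterior probabilities as supports.
    """
    if n_iter < sample_freq:
        raise ValueError("n_iter must be >= sample_freq")
    partitioned = isinstance(data, PartitionedAlignment)
    labels = data.taxa if partitioned else [r for r, _ in _coerce_rows(data)]
    n_taxa = len(labels)

    run_splits: list[dict] = []
    trace_records = []
    all_samples = []
    pooled_counts: dict[frozenset, int] = {}
    pooled_total = 0

    for run in range(n_runs):
        rng = random.Random((seed + 1) * 7919 + run)
        nprng = np.random.default_rng([seed, run])
        tree = _distance_start_tree(data, model)
        for nd in tree.preorder_node_iter():
            if nd is not tree.seed_node:
                if nd.edge.length is None or nd.edge.length <= 0:
                    nd.edge.length = 0.05

        ev = _Evaluator(data, model=model, unpaired_model=unpaired_model,
                        doublet_model=doublet_model)
        pinv_part = None
        for k, part in enumerate(ev.parts):
            if part[0] is not None and part[0].k == 4 and part[0].p_inv > 0:
                pinv_part = k
        cur_pinv = ev.parts[pinv_part][0].p_inv if pinv_part is not None else 0.0
        tunable_pinv = pinv_part is not None

        logl = ev.loglik(tree)
        logprior = _branch_logprior(tree, branch_prior_rate)

        n_sampled = 0
        samples = []
        lam = 2.0 * math.log(1.6)
        for it in range(1, n_iter + 1):
            u = rng.random()
            if u < 0.25 and n_taxa >= 4:
                undo = _random_nni_inplace(tree, rng)
                if undo is not None:
                    cand_logl = ev.loglik(tree)
                    if math.log(rng.random() + 1e-300) < cand_logl - logl:
                        logl = cand_logl
                    else:
                        undo()
            elif u < 0.90 or not tunable_pinv:
                edges = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
                nd = edges[rng.randrange(len(edges))]
                old = nd.edge.length
                factor = math.exp(lam * (rng.random() - 0.5))
                nd.edge.length = old * factor
                cand_logl = ev.loglik(tree)
                cand_prior = _branch_logprior(tree, branch_prior_rate)
                accept = math.log(rng.random() + 1e-300) < (
                    (cand_logl + cand_prior) - (logl + logprior) + math.log(factor)
                )
                if accept:
                    logl, logprior = cand_logl, cand_prior
                else:
                    nd.edge.length = old
            else:
                new_p = cur_pinv + (rng.random() - 0.5) * 0.2
                # reflect into [0, 0.95)
                if new_p < 0:
                    new_p = -new_p
                if new_p >= 0.95:
                    new_p = max(0.0, 1.9 - new_p)
                new_p = min(new_p, 0.949)
                ev2 = ev.with_pinv(pinv_part, new_p)
                cand_logl = ev2.loglik(tree)
                if math.log(rng.random() + 1e-300) < cand_logl - logl:
                    cur_pinv, logl, ev = new_p, cand_logl, ev2
            if it % sample_freq == 0:
                n_sampled += 1
                samples.append(tree.as_string(schema="newick").strip())
                trace_records.append(
                    {"run": run, "iteration": it, "logL": logl, "p_inv": cur_pinv}
                )
        burn = int(math.ceil(n_sampled * burnin_frac))
        # recount splits over post-burnin samples only
        post_counts: dict[frozenset, int] = {}
        kept = samples[burn:]
        for nwk in kept:
            t = dendropy.Tree.get(data=nwk, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
            for side in tree_splits(t):
                post_counts[side] = post_counts.get(side, 0) + 1
        denom = max(len(kept), 1)
        run_splits.append({s: c / denom for s, c in post_counts.items()})
        for s, c in post_counts.items():
            pooled_counts[s] = pooled_counts.get(s, 0) + c
        pooled_total += denom
        all_samples.append(kept)

    split_posterior = {s: c / pooled_total for s, c in pooled_counts.items()}
    # ASDSF over splits with pooled frequency >= 0.1
    interesting = [s for s, f in split_posterior.items() if f >= 0.1]
    if interesting and n_runs > 1:
        sds = []
        for s in interesting:
            fs = np.array([rs.get(s, 0.0) for rs in run_splits])
            sds.append(float(np.std(fs, ddof=1)))
        asdsf = float(np.mean(sds))
    else:
        asdsf = 0.0
    consensus = consensus_from_splits(split_posterior, labels, cutoff=0.5, scale=1.0)
    return BayesResult(
        consensus=consensus,
        split_posterior=split_posterior,
        asdsf=asdsf,
        converged=asdsf < 0.01,
        trace=pd.DataFrame(trace_records),
        samples=all_samples,
    )


def _random_nni_inplace(tree, rng):
    """Apply a random NNI in place; returns an undo closure (or None)."""
    edges = _internal_edges(tree)
    if not edges:
        return None
    e = edges[rng.randrange(len(edges))]
    v, u = e.head_node, e.tail_node
    vkids = v.child_nodes()
    ukids = [c for c in u.child_nodes() if c is not v]
    if len(vkids) < 2 or not ukids:
        return None
    s = ukids[rng.randrange(len(ukids))]
    c = vkids[rng.randrange(len(vkids))]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)

    def undo():
        u.remove_child(c)
        v.remove_child(s)
        u.add_child(s)
        v.add_child(c)

    return undo


def _with_pinv(model: SubstitutionModel, p: float) -> SubstitutionModel:
    if model is None:
        return None
    if abs(model.p_inv - p) < 1e-15:
        return model
    m = SubstitutionModel.__new__(SubstitutionModel)
    m.__dict__.update(model.__dict__)
    m.p_inv = float(p)
    m._charmap_cache = model._charmap_cache
    return m


def _branch_logprior(tree, rate: float) -> float:
    total = 0.0
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        b = nd.edge.length or 0.0
        total += math.log(rate) - rate * b
    return total
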