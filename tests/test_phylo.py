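import itertools
import math
import random

import numpy as np
import pytest

from itsphylo import core_io
from itsphylo.phylo import (
    DOUBLET_STATES,
    NUC_STATES,
    PartitionedAlignment,
    SubstitutionModel,
    bayes_mcmc,
    bootstrap,
    likelihood,
    ml_distance,
    ml_distance_matrix,
    ml_search,
    mp_search,
    nj_tree,
    parsimony_score,
    random_topology,
    rf_distance,
    tree_splits,
)


# --- brute-force oracles ----------------------------------------------------

def brute_force_loglik(tree, rows, model):
    """Sum over all internal-state assignments (tiny trees only)."""
    data = dict(rows)
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    n_sites = len(next(iter(data.values())))
    k = model.k
    P = {id(nd): model.transition_matrix(nd.edge.length or 0.0)
         for nd in nodes if nd is not tree.seed_node}
    total = 0.0
    rates, weights = model.rate_categories()
    Pr = {}
    for r in rates:
        Pr[r] = {id(nd): model.transition_matrix((nd.edge.length or 0.0) * r)
                 for nd in nodes if nd is not tree.seed_node}
    for site in range(n_sites):
        site_l = 0.0
        allowed = {}
        for nd in nodes:
            if nd.is_leaf():
                vec = model.char_vector(data[nd.taxon.label][site])
                allowed[id(nd)] = [i for i in range(k) if vec[i] > 0]
        if model.p_inv > 0:
            for x in range(k):
                if all(x in allowed[id(nd)] for nd in nodes if nd.is_leaf()):
                    site_l += model.p_inv * model.pi[x]
        for r, w in zip(rates, weights):
            rate_l = 0.0
            for assign in itertools.product(range(k), repeat=len(internal)):
                states = {id(nd): s for nd, s in zip(internal, assign)}
                p = model.pi[states[id(tree.seed_node)]]
                for nd in nodes:
                    if nd is tree.seed_node:
                        continue
                    ps = states[id(nd.parent_node)]
                    if nd.is_leaf():
                        p *= sum(Pr[r][id(nd)][ps, x] for x in allowed[id(nd)])
                    else:
                        p *= Pr[r][id(nd)][ps, states[id(nd)]]
                rate_l += p
            site_l += (1.0 - model.p_inv) * w * rate_l
        total += math.log(site_l)
    return total


def brute_force_parsimony(tree, rows, k=4):
    """Minimum mutation count over all internal-state assignments."""
    data = dict(rows)
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    charsets = {"A": {0}, "C": {1}, "G": {2}, "U": {3},
                "-": set(range(k)), "?": set(range(k))}
    n_sites = len(next(iter(data.values())))
    total = 0
    for site in range(n_sites):
        best = None
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {id(nd): s for nd, s in zip(internal, assign)}
            cost = 0
            ok = True
            for nd in nodes:
                if nd is tree.seed_node:
                    continue
                ps = states[id(nd.parent_node)]
                if nd.is_leaf():
                    cs = charsets[data[nd.taxon.label][site]]
                    if ps not in cs:
                        cost += 1
                else:
                    if states[id(nd)] != ps:
                        cost += 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


# --- distances ---------------------------------------------------------------

class TestDistance:
    def test_identical_is_zero(self):
        m = SubstitutionModel.jc(4)
        assert ml_distance("ACGUACGU", "ACGUACGU", m) == 0.0

    @pytest.mark.parametrize("ndiff", [5, 10, 20])
    def test_jc_closed_form(self, ndiff):
        m = SubstitutionModel.jc(4)
        a = "A" * 100
        b = "G" * ndiff + "A" * (100 - ndiff)
        p = ndiff / 100
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert ml_distance(a, b, m) == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self, rng):
        m = SubstitutionModel.gtr(exch=[1, 2, 1, 1, 3, 1], pi=[0.3, 0.2, 0.3, 0.2])
        for _ in range(5):
            a = "".join(rng.choice("ACGU") for _ in range(80))
            b = "".join(rng.choice("ACGU") for _ in range(80))
            assert ml_distance(a, b, m) == pytest.approx(ml_distance(b, a, m), abs=1e-9)

    def test_empty_overlap_rejected(self):
        m = SubstitutionModel.jc(4)
        with pytest.raises(ValueError, match="overlap"):
            ml_distance("--AA", "AA--", m, ids=("x", "y"))

    def test_saturation_capped_with_warning(self):
        m = SubstitutionModel.jc(4)
        a = "ACGU" * 10
        b = "CAUG" * 10  # every site differs
        with pytest.warns(UserWarning, match="saturated"):
            d = ml_distance(a, b, m, max_distance=5.0)
        assert d == 5.0


class TestNJ:
    def test_three_point_formulas(self):
        t = nj_tree(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]]), ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_matrix_recovered_exactly(self, rng):
        for _ in range(10):
            labels = [f"t{i}" for i in range(6)]
            true = random_topology(labels, rng)
            for nd in true.preorder_node_iter():
                if nd is not true.seed_node:
                    nd.edge.length = rng.uniform(0.3, 2.0)
            pdm = true.phylogenetic_distance_matrix()
            tx = {t.label: t for t in true.taxon_namespace}
            D = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    if i != j:
                        D[i, j] = pdm.distance(tx[labels[i]], tx[labels[j]])
            rec = nj_tree(D, labels)
            assert rf_distance(rec, true) == 0

    def test_equal_distances_zero_internal_edges(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        t = nj_tree(D, list("abcd"))
        for nd in t.preorder_node_iter():
            if not nd.is_leaf() and nd is not t.seed_node:
                assert nd.edge.length == pytest.approx(0.0, abs=1e-12)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = float("nan")
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(D, list("abc"))


class TestParsimony:
    def test_constant_columns_score_zero(self):
        t = core_io.read_newick("((A,B),(C,D));")
        assert parsimony_score(t, [("A", "AAA"), ("B", "AAA"), ("C", "AAA"), ("D", "AAA")]) == 0

    def test_single_informative_column(self):
        t = core_io.read_newick("((A,B),(C,D));")
        rows = [("A", "A"), ("B", "A"), ("C", "G"), ("D", "G")]
        assert parsimony_score(t, rows) == 1
        assert brute_force_parsimony(t, rows) == 1

    def test_matches_bruteforce_small(self, rng):
        for _ in range(10):
            labels = list("ABCDE")
            t = random_topology(labels, rng)
            rows = [(lab, "".join(rng.choice("ACGU-") for _ in range(3)))
                    for lab in labels]
            assert parsimony_score(t, rows) == brute_force_parsimony(t, rows)

    def test_search_beats_random_trees(self, rng):
        labels = list("ABCDEF")
        rows = [(lab, "".join(rng.choice("ACGU") for _ in range(30))) for lab in labels]
        best_trees, best_score = mp_search(rows, n_starts=3, seed=1)
        for _ in range(5):
            t = random_topology(labels, rng)
            assert best_score <= parsimony_score(t, rows)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="4 taxa"):
            mp_search([("A", "AC"), ("B", "AC"), ("C", "AC")])


class TestLikelihood:
    def test_zero_branch_identical_site_is_log_pi(self):
        t = core_io.read_newick("(A:0.0000001,B:0.0000001);")
        m = SubstitutionModel.jc(4)
        ll = likelihood(t, [("A", "C"), ("B", "C")], model=m)
        assert ll == pytest.approx(math.log(0.25), abs=1e-4)

    def test_two_taxon_closed_form(self):
        m = SubstitutionModel.jc(4)
        t = core_io.read_newick("(A:0.05,B:0.05);")
        rows = [("A", "ACGUA"), ("B", "ACGUG")]
        d = 0.1
        p_same = 0.25 + 0.75 * math.exp(-4 * d / 3)
        p_diff = 0.25 - 0.25 * math.exp(-4 * d / 3)
        expected = 4 * math.log(0.25 * p_same) + math.log(0.25 * p_diff / 3 * 3)
        assert likelihood(t, rows, model=m) == pytest.approx(expected, abs=1e-10)

    def test_matches_bruteforce_small_trees(self, rng):
        m_plain = SubstitutionModel.gtr(exch=[1, 2, 1, 1, 3, 1],
                                        pi=[0.3, 0.2, 0.3, 0.2])
        m_ig = SubstitutionModel.gtr(p_inv=0.3, gamma_alpha=0.7)
        for m in (m_plain, m_ig):
            for _ in range(4):
                labels = list("ABCDE")
                t = random_topology(labels, rng)
                for nd in t.preorder_node_iter():
                    if nd is not t.seed_node:
                        nd.edge.length = rng.uniform(0.05, 0.8)
                rows = [(lab, "".join(rng.choice("ACGU") for _ in range(3)))
                        for lab in labels]
                assert likelihood(t, rows, model=m) == pytest.approx(
                    brute_force_loglik(t, rows, m), abs=1e-8
                )

    def test_empty_paired_partition_reduces_to_plain(self):
        from itsphylo.struct_align import AlignedRow, StructuralAlignment

        rows = [
            AlignedRow("A", "ACGUACGU", "........"),
            AlignedRow("B", "ACGAACGU", "........"),
            AlignedRow("C", "ACGUACGA", "........"),
            AlignedRow("D", "GCGUACGU", "........"),
        ]
        aln = StructuralAlignment(rows)

        class EmptyMask:
            def pairs(self):
                return []

        part = PartitionedAlignment.from_alignment(aln, EmptyMask())
        t = core_io.read_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.05);")
        gtr_i = SubstitutionModel.gtr(p_inv=0.2)
        ll_part = likelihood(t, part, unpaired_model=gtr_i,
                             doublet_model=SubstitutionModel.doublet())
        ll_plain = likelihood(t, aln.nucleotide_rows(), model=gtr_i)
        assert ll_part == pytest.approx(ll_plain, abs=1e-9)

    def test_doublet_strand_symmetry(self):
        # with the symmetric default doublet model, swapping the two
        # columns of every doublet site leaves the likelihood unchanged
        taxa = ["A", "B", "C", "D"]
        drows = {"A": ["GC", "AU"], "B": ["GC", "GU"], "C": ["GU", "AU"],
                 "D": ["CG", "UA"]}
        swapped = {t: [d[::-1] for d in drows[t]] for t in taxa}
        urows = {t: "" for t in taxa}
        part1 = PartitionedAlignment(taxa, [(0, 1), (2, 3)], drows, urows)
        part2 = PartitionedAlignment(taxa, [(0, 1), (2, 3)], swapped, urows)
        t = core_io.read_newick("((A:0.1,B:0.2):0.1,(C:0.15,D:0.1):0.1);")
        dbl = SubstitutionModel.doublet()
        gtr = SubstitutionModel.gtr()
        ll1 = likelihood(t, part1, unpaired_model=gtr, doublet_model=dbl)
        ll2 = likelihood(t, part2, unpaired_model=gtr, doublet_model=dbl)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_nonreversible_model_rejected(self):
        Q = np.array([
            [-3.0, 1.0, 1.0, 1.0],
            [0.5, -2.5, 1.0, 1.0],
            [1.0, 1.0, -3.0, 1.0],
            [1.0, 1.0, 1.0, -3.0],
        ])
        with pytest.raises(ValueError, match="reversible"):
            SubstitutionModel(NUC_STATES, Q, np.full(4, 0.25))


class TestMLSearch:
    def test_recovers_simulated_topology(self):
        from itsphylo.synthetic import SimulationConfig, simulate_evolution

        cfg = SimulationConfig(n_taxa=6, seed=3)
        _, aln, truth = simulate_evolution(cfg)
        tree, ll = ml_search(aln.nucleotide_rows(), model=SubstitutionModel.gtr())
        assert rf_distance(tree, truth.tree) == 0

    def test_loglik_not_below_nj_start(self):
        from itsphylo.synthetic import SimulationConfig, simulate_evolution
        from itsphylo.phylo import _distance_start_tree, _Evaluator, _optimize_branch_lengths

        cfg = SimulationConfig(n_taxa=6, seed=9)
        _, aln, _ = simulate_evolution(cfg)
        model = SubstitutionModel.gtr()
        ev = _Evaluator(aln.nucleotide_rows(), model=model)
        start = _distance_start_tree(aln.nucleotide_rows(), model)
        for nd in start.preorder_node_iter():
            if nd is not start.seed_node and (nd.edge.length or 0) <= 0:
                nd.edge.length = 1e-6
        ll_start = _optimize_branch_lengths(start, ev)
        _, ll_final = ml_search(aln.nucleotide_rows(), model=model)
        assert ll_final >= ll_start - 1e-6

    def test_taxon_order_invariance(self):
        from itsphylo.synthetic import SimulationConfig, simulate_evolution

        cfg = SimulationConfig(n_taxa=5, seed=13)
        _, aln, _ = simulate_evolution(cfg)
        rows = aln.nucleotide_rows()
        m = SubstitutionModel.gtr()
        t1, _ = ml_search(rows, model=m)
        t2, _ = ml_search(rows[::-1], model=m)
        assert set(tree_splits(t1)) == set(tree_splits(t2))


class TestBootstrap:
    def _congruent_rows(self):
        # every site supports ((A,B),(C,D))
        return [("A", "AAAAAAAAAA"), ("B", "AAAAAAAAAA"),
                ("C", "GGGGGGGGGG"), ("D", "GGGGGGGGGG"),
                ("E", "GGGGGGGGGG")]

    def test_congruent_data_full_support(self):
        rows = [("A", "A" * 20 + "C" * 20), ("B", "A" * 20 + "C" * 20),
                ("C", "G" * 20 + "U" * 20), ("D", "G" * 20 + "U" * 20)]
        t = bootstrap(rows, "nj", model=SubstitutionModel.jc(4), n_reps=30, seed=5)
        sups = [s for s in tree_splits(t).values() if s is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_identical(self):
        rows = self._congruent_rows()
        t1 = bootstrap(rows, "nj", model=SubstitutionModel.jc(4), n_reps=20, seed=7)
        t2 = bootstrap(rows, "nj", model=SubstitutionModel.jc(4), n_reps=20, seed=7)
        assert core_io.write_newick(t1) == core_io.write_newick(t2)

    def test_cutoff_above_one_gives_star(self):
        rows = self._congruent_rows()
        t = bootstrap(rows, "nj", model=SubstitutionModel.jc(4), n_reps=10,
                      cutoff=1.01, seed=1)
        assert len(tree_splits(t)) == 0

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap(self._congruent_rows(), "nj", model=SubstitutionModel.jc(4),
                      n_reps=0)


class TestBayes:
    def test_same_seed_identical_chain(self):
        rows = [("A", "ACGUACGUAA"), ("B", "ACGUACGUAC"),
                ("C", "ACGAACGUGG"), ("D", "GCGAACGUGG")]
        m = SubstitutionModel.gtr(p_inv=0.2)
        r1 = bayes_mcmc(rows, model=m, n_iter=2000, seed=3)
        r2 = bayes_mcmc(rows, model=m, n_iter=2000, seed=3)
        assert r1.samples == r2.samples
        assert r1.asdsf == r2.asdsf

    def test_three_taxa_no_nontrivial_splits(self):
        rows = [("A", "ACGUACGU"), ("B", "ACGAACGU"), ("C", "GCGUACGU")]
        res = bayes_mcmc(rows, model=SubstitutionModel.jc(4), n_iter=1000, seed=1)
        assert res.split_posterior == {}
        assert res.converged

    def test_iteration_validation(self):
        rows = [("A", "AC"), ("B", "AC"), ("C", "AC"), ("D", "AC")]
        with pytest.raises(ValueError, match="n_iter"):
            bayes_mcmc(rows, model=SubstitutionModel.jc(4), n_iter=10, sample_freq=100)


class TestModelConstruction:
    def test_gamma_rates_mean_one(self):
        m = SubstitutionModel.gtr(gamma_alpha=0.5)
        rates, weights = m.rate_categories()
        assert np.dot(rates, weights) == pytest.approx(1.0)
        assert len(rates) == 4
        assert list(rates) == sorted(rates)

    def test_q_normalised_to_one_sub_per_site(self):
        m = SubstitutionModel.gtr(exch=[1, 5, 1, 1, 5, 1], pi=[0.4, 0.1, 0.4, 0.1])
        assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0)

    def test_doublet_single_change_only(self):
        m = SubstitutionModel.doublet()
        for i, di in enumerate(DOUBLET_STATES):
            for j, dj in enumerate(DOUBLET_STATES):
                ndiff = (di[0] != dj[0]) + (di[1] != dj[1])
                if ndiff == 2:
                    assert m.Q[i, j] == 0.0

    def test_empirical_gtr_from_alignment(self):
        rows = [("a", "ACGUACGUGG"), ("b", "ACGUACGAGG"), ("c", "ACGCACGUGG")]
        m = SubstitutionModel.gtr_from_alignment(rows)
        assert m.pi.sum() == pytest.approx(1.0)
        assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0)
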