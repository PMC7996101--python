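import math
import random

import numpy as np
import pytest

from itsphylo import core_io
from itsphylo.annotation import build_consensus_structure, check_its2_hallmarks
from itsphylo.cbc import classify_doublet_change, scan_alignment
from itsphylo.folding import VALID_PAIRS, fold_mfe
from itsphylo.phylo import DOUBLET_STATES, SubstitutionModel
from itsphylo.synthetic import (
    SimulationConfig,
    make_its2_toy,
    simulate_evolution,
    simulate_tree,
)


class TestSimulateTree:
    def test_minimum_taxa_enforced(self):
        with pytest.raises(ValueError, match="n_taxa"):
            simulate_tree(2)

    def test_deterministic_per_seed(self):
        a = core_io.write_newick(simulate_tree(8, seed=42))
        b = core_io.write_newick(simulate_tree(8, seed=42))
        assert a == b
        c = core_io.write_newick(simulate_tree(8, seed=43))
        assert a != c

    def test_branch_lengths_positive(self):
        t = simulate_tree(10, seed=5)
        for nd in t.preorder_node_iter():
            if nd is not t.seed_node:
                assert nd.edge.length > 0

    def test_leaf_count(self):
        t = simulate_tree(9, seed=1)
        assert len([1 for _ in t.leaf_node_iter()]) == 9

    def test_cherry_count_matches_yule_expectation(self):
        # for the Yule process E[#cherries] = n/3, Var = 2n/45
        n, reps = 9, 200
        counts = []
        for s in range(reps):
            t = simulate_tree(n, seed=s)
            cherries = 0
            for nd in t.preorder_node_iter():
                kids = nd.child_nodes()
                if len(kids) == 2 and all(c.is_leaf() for c in kids):
                    cherries += 1
            counts.append(cherries)
        mean = np.mean(counts)
        se = math.sqrt(2 * n / 45 / reps)
        assert abs(mean - n / 3) < 3 * se


class TestSimulateEvolution:
    def test_zero_rates_give_identical_leaves_and_empty_census(self):
        cfg = SimulationConfig(n_taxa=5, seed=2, paired_rate=0.0, unpaired_rate=0.0)
        recs, aln, truth = simulate_evolution(cfg)
        assert len({r.seq for r in aln.rows}) == 1
        cons = build_consensus_structure(aln)
        rep = scan_alignment(aln, cons)
        assert rep.n_hcbc_sites == 0 and rep.n_cbc_sites == 0
        assert truth.event_log.empty

    def test_pairing_preserving_kernel(self):
        cfg = SimulationConfig(n_taxa=6, seed=7, tree_scale=0.4)
        _, aln, truth = simulate_evolution(cfg)
        paired = truth.event_log[truth.event_log.site_j >= 0]
        assert paired.pairing_preserving.all()
        for _, ev in paired.iterrows():
            assert ev["from"] in VALID_PAIRS and ev["to"] in VALID_PAIRS

    def test_event_log_replays_to_leaves(self):
        cfg = SimulationConfig(n_taxa=5, seed=8, tree_scale=0.3)
        _, aln, truth = simulate_evolution(cfg)
        # replay events root -> leaf along the tree path
        root = truth.root.residues
        log = truth.event_log

        def replay(leaf):
            seq = list(root)
            path = []
            nd = leaf
            while nd.parent_node is not None:
                path.append(nd)
                nd = nd.parent_node
            for nd in reversed(path):
                name = nd.taxon.label if nd.taxon else nd._sim_name
                for _, ev in log[log.branch == name].iterrows():
                    if ev.site_j >= 0:
                        seq[ev.site_i], seq[ev.site_j] = ev["to"][0], ev["to"][1]
                    elif ev["to"] != "-":
                        seq[ev.site_i] = ev["to"]
            return "".join(seq)

        for leaf in truth.tree.leaf_node_iter():
            expected = aln.row(leaf.taxon.label).seq.replace("-", "")
            assert replay(leaf).replace("-", "") == expected

    def test_deterministic_outputs(self):
        cfg = SimulationConfig(n_taxa=5, seed=3)
        r1 = simulate_evolution(cfg)
        r2 = simulate_evolution(SimulationConfig(n_taxa=5, seed=3))
        assert [x.seq for x in r1[1].rows] == [x.seq for x in r2[1].rows]
        assert core_io.write_newick(r1[2].tree) == core_io.write_newick(r2[2].tree)

    def test_invalid_paired_pi_rejected(self):
        cfg = SimulationConfig(n_taxa=4, seed=1, paired_pi={"AA": 0.5, "GC": 0.5})
        with pytest.raises(ValueError, match="invalid doublet"):
            simulate_evolution(cfg)

    def test_hcbc_truth_matches_census(self):
        cfg = SimulationConfig(n_taxa=6, seed=21, tree_scale=0.3)
        _, aln, truth = simulate_evolution(cfg)
        cons = build_consensus_structure(aln, pair_threshold=0.0)
        rep = scan_alignment(aln, cons)
        assert set(rep.sites("hCBC")) == truth.hcbc_truth_sites()
        assert set(rep.sites("CBC")) == truth.cbc_truth_sites()

    def test_cbc_frequency_matches_transition_matrix(self):
        # one pair site on a two-leaf cherry with long branches: the
        # Monte-Carlo CBC frequency from the jump-chain simulator must
        # match the exact matrix-exponential calculation
        t = 1.5
        reps = 500
        pi16 = np.zeros(16)
        valid = sorted(VALID_PAIRS)
        for d in valid:
            pi16[DOUBLET_STATES.index(d)] = 1 / 6
        dmodel = SubstitutionModel.doublet(pi=pi16)
        P = dmodel.transition_matrix(t)
        exact = 0.0
        for di, d in enumerate(DOUBLET_STATES):
            if pi16[di] == 0:
                continue
            for ai, a in enumerate(DOUBLET_STATES):
                for bi, b in enumerate(DOUBLET_STATES):
                    if classify_doublet_change(a, b) == "CBC":
                        exact += pi16[di] * P[di, ai] * P[di, bi]
        # Monte Carlo with the simulator's Gillespie kernel
        rng = random.Random(99)
        Q = dmodel.Q
        hits = 0
        for _ in range(reps):
            d0 = rng.choices(valid, weights=[1 / 6] * 6)[0]

            def evolve(d):
                time = 0.0
                while True:
                    di = DOUBLET_STATES.index(d)
                    rate = -Q[di, di]
                    time += rng.expovariate(rate)
                    if time >= t:
                        return d
                    probs = np.clip(Q[di], 0, None)
                    probs[di] = 0
                    d = rng.choices(DOUBLET_STATES, weights=probs / probs.sum())[0]

            a, b = evolve(d0), evolve(d0)
            if classify_doublet_change(a, b) == "CBC":
                hits += 1
        mc = hits / reps
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) < 4 * se


class TestIts2Toy:
    def test_hallmark_toggles_independent(self):
        for motif in (True, False):
            for uu in (True, False):
                ss, f58, f28 = make_its2_toy(motif=motif, uu=uu)
                rep = check_its2_hallmarks(ss, f58, f28)
                assert rep.motif_found == motif
                assert rep.uu_mismatch_found == uu

    def test_folding_recovers_designed_pairs(self):
        total, recovered = 0, 0
        for seed in range(20):
            ss, _, _ = make_its2_toy(seed=seed)
            res = fold_mfe(ss.record)
            true = set(ss.structure.pairs())
            total += len(true)
            recovered += len(true & set(res.structure.pairs()))
        assert recovered / total >= 0.9

    def test_deterministic_per_seed(self):
        a = make_its2_toy(seed=3)[0]
        b = make_its2_toy(seed=3)[0]
        assert a.residues == b.residues
        assert a.structure == b.structure
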