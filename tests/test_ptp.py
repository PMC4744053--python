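"""Two-rate Poisson branch model: likelihoods, search, parameter recovery."""

import math
import random

import dendropy
import numpy as np
import pytest

from motudelim.ptp import ptp_delimit, ptp_loglik
from motudelim.synthetic_data import SimConfig, SpeciesSpec, simulate_tree_dataset


def two_tip_tree(b1: float = 0.1, b2: float = 0.1) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(["a", "b"])
    t = dendropy.Tree(taxon_namespace=taxa)
    for label, b in (("a", b1), ("b", b2)):
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nd.edge.length = b
        t.seed_node.add_child(nd)
    t.is_rooted = True
    return t


def random_two_rate_tree(n_species: int, tips_per: int, lam_w: float, lam_b: float,
                         seed: int) -> tuple[dendropy.Tree, dict[str, str]]:
    """Balanced species clades: between-species edges ~Exp(lam_b), within ~Exp(lam_w)."""
    rng = np.random.default_rng(seed)
    labels = [f"s{i}_{k}" for i in range(n_species) for k in range(tips_per)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    truth = {}
    species_nodes = []
    for i in range(n_species):
        sp = dendropy.Node()
        sp.edge.length = float(rng.exponential(1 / lam_b))
        species_nodes.append(sp)
        # caterpillar inside each species
        current = sp
        tips = [f"s{i}_{k}" for k in range(tips_per)]
        for k, lab in enumerate(tips):
            truth[lab] = f"sp{i}"
            tip = dendropy.Node(taxon=taxa.get_taxon(lab))
            tip.edge.length = float(rng.exponential(1 / lam_w))
            if k < tips_per - 1:
                inner = dendropy.Node()
                inner.edge.length = float(rng.exponential(1 / lam_w))
                current.add_child(tip)
                current.add_child(inner)
                current = inner
            else:
                current.add_child(tip)
    # ladder of species clades joined by between-species internal edges
    current = tree.seed_node
    for i, sp in enumerate(species_nodes):
        if i < n_species - 1:
            inner = dendropy.Node()
            inner.edge.length = float(rng.exponential(1 / lam_b))
            current.add_child(sp)
            current.add_child(inner)
            current = inner
        else:
            current.add_child(sp)
    return tree, truth


class TestLogLikelihood:
    def test_two_tip_single_species_closed_form(self):
        t = two_tip_tree(0.1, 0.1)
        lam_w, lam_b, ll = ptp_loglik(t, {"a": "x", "b": "x"})
        assert lam_w == pytest.approx(10.0)
        assert lam_b is None
        assert ll == pytest.approx(2 * (math.log(10) - 1), abs=1e-12)
        assert ll == pytest.approx(2.6052, abs=1e-4)

    def test_two_tip_two_species_symmetric_loglik(self):
        t = two_tip_tree(0.1, 0.1)
        lam_w, lam_b, ll = ptp_loglik(t, {"a": "x", "b": "y"})
        assert lam_w is None
        assert lam_b == pytest.approx(10.0)
        assert ll == pytest.approx(2 * (math.log(10) - 1), abs=1e-12)

    def test_disconnected_species_rejected(self):
        tree, truth = random_two_rate_tree(3, 3, 100, 5, seed=1)
        bad = dict(truth)
        bad["s0_0"], bad["s2_0"] = bad["s2_0"], bad["s0_0"]  # interleave two species
        with pytest.raises(ValueError, match="connected"):
            ptp_loglik(tree, bad)

    def test_true_partition_beats_one_species(self):
        """With strongly separated rates the truth dominates lumping."""
        wins = 0
        for seed in range(20):
            tree, truth = random_two_rate_tree(2, 4, lam_w=100, lam_b=5, seed=seed)
            _, _, ll_true = ptp_loglik(tree, truth)
            one = {k: "all" for k in truth}
            _, _, ll_one = ptp_loglik(tree, one)
            wins += ll_true > ll_one
        assert wins >= 18

    def test_unrooted_tree_rejected(self):
        t = two_tip_tree()
        t.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            ptp_loglik(t, {"a": "x", "b": "x"})


class TestDelimit:
    def test_two_separated_clades_found(self):
        tree, truth = random_two_rate_tree(2, 5, lam_w=200, lam_b=5, seed=3)
        part, model = ptp_delimit(tree)
        assert part.n_motus == 2
        assert model.lambda_w > model.lambda_b

    def test_uniform_branch_lengths_degenerate_one_species(self):
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
            taxon_namespace=taxa, rng=random.Random(1))
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 0.05
        tree.is_rooted = True
        with pytest.warns(UserWarning, match="low"):
            part, model = ptp_delimit(tree)
        assert part.n_motus == 1
        assert model.low_confidence

    def test_returned_loglik_at_least_extreme_partitions(self):
        for seed in (1, 2, 3):
            tree, truth = random_two_rate_tree(3, 4, lam_w=60, lam_b=4, seed=seed)
            part, model = ptp_delimit(tree)
            one = {k: "all" for k in truth}
            singles = {k: k for k in truth}
            assert model.log_likelihood >= ptp_loglik(tree, one)[2] - 1e-9
            assert model.log_likelihood >= ptp_loglik(tree, singles)[2] - 1e-9

    def test_heuristic_equals_exhaustive_on_small_trees(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(10)])
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=10,
                taxon_namespace=taxa, rng=random.Random(trial))
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = float(rng.exponential(0.1))
            tree.is_rooted = True
            _, exact = ptp_delimit(tree, exhaustive=True)
            _, heur = ptp_delimit(tree, exhaustive=False)
            assert heur.log_likelihood == pytest.approx(exact.log_likelihood, abs=1e-8)

    def test_species_count_recovery_on_simulated_genealogies(self):
        """>= 80% of seeds recover the generating species count; rates within 2x."""
        hits = 0
        for seed in range(1, 21):
            specs = [SpeciesSpec(f"sp{i}", 4, 0.005, f"G{i // 2}", "T") for i in range(6)]
            cfg = SimConfig(species=specs, target_inter_congeneric=0.10, seed=seed)
            _, tree, truth = simulate_tree_dataset(cfg)
            part, model = ptp_delimit(tree)
            if part.n_motus == 6:
                hits += 1
                # star subtrees: within edges are intra/2 = 0.0025, lam_w = 400
                n_w = sum(1 for nd in tree.preorder_node_iter()
                          if nd.parent_node is not None) - len(
                              [n for n in tree.preorder_node_iter()])
                if model.lambda_w and model.lambda_b:
                    assert model.lambda_w / model.lambda_b > 2
        assert hits >= 16

    def test_single_species_simulation_one_group(self):
        specs = [SpeciesSpec("only", 6, 0.004, "G", "T")]
        cfg = SimConfig(species=specs, target_inter_congeneric=0.1, seed=2)
        _, tree, truth = simulate_tree_dataset(cfg)
        part, model = ptp_delimit(tree)
        assert part.n_motus == 1
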