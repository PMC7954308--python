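"""Pruning correctness: enumeration oracles, rerooting, gradients."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from multihit import CodonAlignment, TransitionKernel
from multihit.likelihood import make_codon_engine
from multihit.ratematrix import MODEL_SPECS
from multihit.tree import PhyloTree


def brute_force_site_loglik(aln, tree, kernel, site):
    """Sum the joint likelihood over all internal-node codon assignments."""
    leaf_map = tree.match_taxa(aln.taxa)
    S = kernel.freqs.shape[0]
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    total = 0.0
    for k in range(kernel.n_classes):
        P = {
            v: kernel.transition(tree.edge_length[v], k)
            for v in range(tree.n_nodes - 1)
        }
        lik_k = 0.0
        for assign in itertools.product(range(S), repeat=len(internals)):
            states = dict(zip(internals, assign))
            p = kernel.freqs[states[tree.root]]
            for v in range(tree.n_nodes - 1):
                parent_state = states[tree.parent[v]]
                if tree.children[v]:
                    p *= P[v][parent_state, states[v]]
                else:
                    part = aln.leaf_partial(leaf_map[v], site)
                    p *= P[v][parent_state] @ part
                if p == 0.0:
                    break
            lik_k += p
        total += kernel.class_weights[k] * lik_k
    return np.log(total)


def random_params(universal, seed):
    from multihit.simulate import uniform_params

    r = np.random.default_rng(seed)
    return uniform_params(
        universal,
        omega=np.sort(r.uniform(0.05, 2.0, 2)),
        weights=np.array([0.6, 0.4]),
        delta=r.uniform(0, 1),
        psi_s=r.uniform(0, 3),
        psi=r.uniform(0, 1),
        theta=np.insert(r.uniform(0.3, 2.5, 5), 1, 1.0),
    )


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_three_taxon_enumeration(self, universal, three_taxon_tree, seed):
        params = random_params(universal, seed)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C"], ["ATGTCA", "ATGAGT", "ACGTCC"], universal
        )
        engine = make_codon_engine(aln, three_taxon_tree)
        got = engine.site_loglik(kernel, three_taxon_tree.edge_length)
        for site in range(aln.n_sites):
            want = brute_force_site_loglik(aln, three_taxon_tree, kernel, site)
            assert got[site] == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_taxon_enumeration(self, universal, seed):
        tree = PhyloTree.from_newick(
            "((A:0.1,B:0.4):0.15,(C:0.3,D:0.05):0.2);"
        )
        params = random_params(universal, seed + 100)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C", "D"],
            ["TCAATG", "AGCATG", "TCGACG", "AGTATG"],
            universal,
        )
        engine = make_codon_engine(aln, tree)
        got = engine.site_loglik(kernel, tree.edge_length)
        for site in range(aln.n_sites):
            want = brute_force_site_loglik(aln, tree, kernel, site)
            assert got[site] == pytest.approx(want, rel=1e-10)

    def test_ambiguous_and_missing_columns(self, universal, three_taxon_tree):
        params = random_params(universal, 7)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C"],
            ["---TCR", "NNNAGT", "---TCC"],
            universal,
        )
        engine = make_codon_engine(aln, three_taxon_tree)
        got = engine.site_loglik(kernel, three_taxon_tree.edge_length)
        # all-missing column has likelihood exactly 1
        assert got[0] == pytest.approx(0.0, abs=1e-12)
        want = brute_force_site_loglik(aln, three_taxon_tree, kernel, 1)
        assert got[1] == pytest.approx(want, rel=1e-10)


class TestInvariances:
    def test_rerooting_leaves_likelihood_unchanged(self, universal):
        """Reversibility: the arbitrary root placement is immaterial."""
        params = random_params(universal, 3)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        seqs = ["TCAATGAAA", "AGCATGAAG", "TCGACGCAA", "AGTATAAAA"]
        names = ["A", "B", "C", "D"]
        aln = CodonAlignment.from_sequences(names, seqs, universal)
        rootings = [
            "((A:0.1,B:0.4):0.15,(C:0.3,D:0.05):0.2);",
            "(A:0.1,B:0.4,(C:0.3,D:0.05):0.35);",
            "(C:0.3,D:0.05,(A:0.1,B:0.4):0.35);",
        ]
        vals = []
        for nwk in rootings:
            tree = PhyloTree.from_newick(nwk)
            engine = make_codon_engine(aln, tree)
            vals.append(engine.loglik(kernel, tree.edge_length))
        assert vals[0] == pytest.approx(vals[1], abs=1e-8)
        assert vals[0] == pytest.approx(vals[2], abs=1e-8)

    def test_omega_class_permutation_invariance(self, universal):
        params = random_params(universal, 11)
        permuted = replace(
            params,
            omega=params.omega[::-1].copy(),
            weights=params.weights[::-1].copy(),
        )
        tree = PhyloTree.from_newick("(A:0.2,B:0.35,C:0.15);")
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C"], ["ATGTCA", "ATGAGT", "ACGTCC"], universal
        )
        engine = make_codon_engine(aln, tree)
        k1 = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        k2 = TransitionKernel(permuted, MODEL_SPECS["3H+"], universal)
        assert engine.loglik(k1, tree.edge_length) == pytest.approx(
            engine.loglik(k2, tree.edge_length), abs=1e-10
        )

    def test_single_taxon_likelihood_is_frequency(self, universal):
        params = random_params(universal, 5)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        tree = PhyloTree(
            parent=np.array([-1]), edge_length=np.array([0.0]),
            leaf_taxon=["A"],
        )
        aln = CodonAlignment.from_sequences(["A"], ["ATG"], universal)
        engine = make_codon_engine(aln, tree)
        got = engine.site_loglik(kernel, tree.edge_length)
        f_atg = kernel.freqs[universal.index("ATG")]
        assert got[0] == pytest.approx(np.log(f_atg), rel=1e-12)


class TestGradient:
    def test_branch_gradient_matches_finite_differences(self, universal):
        params = random_params(universal, 23)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        tree = PhyloTree.from_newick(
            "((A:0.08,B:0.45):0.12,(C:0.3,D:0.02):0.22,E:0.6);"
        )
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C", "D", "E"],
            ["TCAATGAAA", "AGCATGAAG", "TCGACGCAA", "AGTATAAAA", "TTGATGAAC"],
            universal,
        )
        engine = make_codon_engine(aln, tree)
        el = tree.edge_length
        lnl, grad, site = engine.loglik_and_branch_grad(kernel, el)
        assert lnl == pytest.approx(engine.loglik(kernel, el), abs=1e-10)
        assert site @ engine.weights == pytest.approx(lnl, abs=1e-10)
        eps = 1e-7
        for e in range(tree.n_edges):
            bumped = el.copy()
            bumped[e] += eps
            fd = (engine.loglik(kernel, bumped) - lnl) / eps
            assert grad[e] == pytest.approx(fd, rel=5e-4, abs=1e-7)
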