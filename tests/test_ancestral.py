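"""Joint ancestral reconstruction and the substitution census."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from multihit import (
    CodonAlignment,
    TransitionKernel,
    census_substitutions,
    census_summary,
    fit_model,
    joint_ancestral_reconstruction,
)
from multihit.ancestral import Reconstruction
from multihit.fit import FitResult, FitSettings
from multihit.likelihood import make_codon_engine
from multihit.ratematrix import MODEL_SPECS
from multihit.simulate import simulate_alignment, uniform_params
from multihit.tree import PhyloTree, random_tree


def fake_fit(params, spec, aln, tree):
    """FitResult wrapper around known parameters (no optimization)."""
    engine = make_codon_engine(aln, tree)
    kernel = TransitionKernel(params, spec, aln.code)
    el = tree.edge_length
    by_class = engine.site_loglik_per_class(kernel, el)
    from scipy.special import logsumexp

    logw = np.log(params.weights)
    pat = logsumexp(by_class + logw[:, None], axis=0)
    _, _, s2p = aln.compress_patterns()
    return FitResult(
        spec=spec,
        params=replace(params, branch_lengths=tree.branch_lengths()),
        lnL=float(pat @ engine.weights),
        site_lnL=pat[s2p],
        site_lnL_by_class=by_class[:, s2p],
        converged=True,
        n_iter=0,
    )


def brute_force_joint(aln, tree, kernel, site, k):
    """Argmax over all internal assignments of the joint site likelihood."""
    leaf_map = tree.match_taxa(aln.taxa)
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    P = {
        v: kernel.transition(tree.edge_length[v], k)
        for v in range(tree.n_nodes - 1)
    }
    best, best_assign = -np.inf, None
    S = len(kernel.freqs)
    for assign in itertools.product(range(S), repeat=len(internals)):
        states = dict(zip(internals, assign))
        p = np.log(kernel.freqs[states[tree.root]])
        for v in range(tree.n_nodes - 1):
            ps = states[tree.parent[v]]
            if tree.children[v]:
                p += np.log(P[v][ps, states[v]])
            else:
                part = aln.leaf_partial(leaf_map[v], site)
                best_leaf = (P[v][ps] * (part > 0)).max()
                p += np.log(best_leaf)
            if p == -np.inf:
                break
        if p > best:
            best, best_assign = p, dict(states)
    return best, best_assign


class TestJointReconstruction:
    def test_identical_leaves_short_branch(self, universal):
        tree = PhyloTree.from_newick("(A:0.01,B:0.01);")
        aln = CodonAlignment.from_sequences(
            ["A", "B"], ["ATGATG", "ATGATG"], universal
        )
        params = uniform_params(universal, omega=0.5)
        fit = fake_fit(params, MODEL_SPECS["1H"], aln, tree)
        recon = joint_ancestral_reconstruction(aln, tree, fit)
        atg = universal.index("ATG")
        assert np.all(recon.node_states[tree.root] == atg)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_four_taxa(self, universal, seed):
        r = np.random.default_rng(seed)
        tree = PhyloTree.from_newick(
            "((A:0.12,B:0.4):0.2,(C:0.33,D:0.06):0.11);"
        )
        params = uniform_params(
            universal,
            omega=0.7,
            delta=r.uniform(0.1, 1),
            psi_s=r.uniform(0, 3),
            psi=r.uniform(0, 1),
            theta=np.insert(r.uniform(0.3, 2.0, 5), 1, 1.0),
        )
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C", "D"],
            ["TCAAAG", "AGCAAA", "TCGCAA", "AGTAGG"],
            universal,
        )
        fit = fake_fit(params, MODEL_SPECS["3H+"], aln, tree)
        kernel = TransitionKernel(params, MODEL_SPECS["3H+"], universal)
        recon = joint_ancestral_reconstruction(aln, tree, fit)
        internals = [v for v in range(tree.n_nodes) if tree.children[v]]
        for site in range(aln.n_sites):
            want_ll, want = brute_force_joint(aln, tree, kernel, site, 0)
            got = {v: recon.node_states[v, site] for v in internals}
            assert recon.joint_loglik[site] == pytest.approx(want_ll, abs=1e-9)
            assert got == want

    def test_reconstruction_without_mh_uses_stepwise_paths(self, universal):
        """Under a 1H fit on 1H data, inferred triple-hit branch events are
        essentially absent away from forced cherry configurations."""
        rng = np.random.default_rng(77)
        tree = random_tree(8, rng, total_length=1.2)
        params = replace(
            uniform_params(universal, omega=0.5),
            branch_lengths=tree.branch_lengths(),
        )
        aln, _ = simulate_alignment(params, "1H", tree, 300, universal, rng)
        fit = fit_model(
            aln, tree, "1H",
            settings=FitSettings(n_omega_classes=1, maxiter=80),
        )
        recon = joint_ancestral_reconstruction(aln, tree, fit)
        events = census_substitutions(recon, universal)
        n3 = int((events["n_changes"] == 3).sum())
        assert n3 <= max(2, 0.01 * len(events))


class TestCensus:
    def test_serine_island_jump_recorded(self, universal):
        tree = PhyloTree.from_newick("(A:0.05,B:0.05);")
        aln = CodonAlignment.from_sequences(
            ["A", "B"], ["AGCATG", "TCAATG"], universal
        )
        params = uniform_params(universal, omega=0.5, delta=0.2, psi_s=5.0)
        fit = fake_fit(params, MODEL_SPECS["3HSI"], aln, tree)
        recon = joint_ancestral_reconstruction(aln, tree, fit)
        events = census_substitutions(recon, universal)
        jumps = events[events["island_jump"]]
        assert len(jumps) == 1
        assert {jumps.iloc[0]["from_codon"], jumps.iloc[0]["to_codon"]} <= {
            "AGC", "TCA", "TCG", "TCT", "AGT", "TCC",
        }
        assert jumps.iloc[0]["n_changes"] == 3
        assert jumps.iloc[0]["from_aa"] == jumps.iloc[0]["to_aa"] == "S"

    def test_no_event_for_identical_states(self, universal):
        tree = PhyloTree.from_newick("(A:0.05,B:0.05);")
        aln = CodonAlignment.from_sequences(
            ["A", "B"], ["ATGATG", "ATGATG"], universal
        )
        params = uniform_params(universal, omega=0.5)
        fit = fake_fit(params, MODEL_SPECS["1H"], aln, tree)
        recon = joint_ancestral_reconstruction(aln, tree, fit)
        events = census_substitutions(recon, universal)
        assert events.empty

    def test_event_count_bounded_by_branches(
        self, universal, small_mh_dataset, hierarchy_fits
    ):
        aln = small_mh_dataset["aln"]
        tree = small_mh_dataset["tree"]
        recon = joint_ancestral_reconstruction(aln, tree, hierarchy_fits["3H+"])
        events = census_substitutions(recon, universal)
        per_site = events.groupby("site").size()
        assert per_site.max() <= tree.n_edges
        assert (events["from_codon"] != events["to_codon"]).all()

    def test_census_summary_and_er_strata(
        self, universal, small_mh_dataset, hierarchy_fits, hierarchy_report
    ):
        aln = small_mh_dataset["aln"]
        tree = small_mh_dataset["tree"]
        recon = joint_ancestral_reconstruction(aln, tree, hierarchy_fits["3H+"])
        events = census_substitutions(
            recon, universal, hierarchy_report.evidence
        )
        assert {"er_3h2h_gt5", "er_2h1h_gt5", "short_branch"} <= set(
            events.columns
        )
        summary = census_summary(events)
        assert summary["n_events"] == len(events)
        assert sum(summary["events_by_class"].values()) == len(events)
        # data were generated with a large island rate: jumps should appear
        assert summary["island_jumps"] >= 1
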