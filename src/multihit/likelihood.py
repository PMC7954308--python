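"""Felsenstein pruning over site-pattern-compressed alignments.

The engine is generic over the state space (61/60 sense codons for the
codon models, 4 nucleotides for the GTR initializer).  It computes per-site
log-likelihoods under a mixture of reversible processes, with per-pattern
rescaling to avoid underflow, and analytic derivatives of the
log-likelihood with respect to every branch length in a single extra
pre-order pass (finite differences over branches would cost one full
likelihood evaluation per branch).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .tree import PhyloTree


class TreeLikelihood:
    """Pruning machinery bound to one tree topology and one set of leaf data.

    Parameters
    ----------
    tree : PhyloTree
        Supplies the topology; branch lengths are passed per call so the
        optimizer can move them without rebuilding the engine.
    leaf_partials : dict[int, ndarray]
        Maps leaf node index to an (n_patterns, n_states) indicator/partial
        array.
    pattern_weights : ndarray
        Multiplicity of each site pattern.
    """

    def __init__(
        self,
        tree: PhyloTree,
        leaf_partials: dict[int, np.ndarray],
        pattern_weights: np.ndarray,
    ) -> None:
        self.tree = tree
        self.leaf_partials = leaf_partials
        self.weights = np.asarray(pattern_weights, dtype=float)
        first = next(iter(leaf_partials.values()))
        self.n_patterns, self.n_states = first.shape
        # leaves whose every pattern is a definite state: their message to
        # the parent is a row gather from P instead of a matmul
        self.leaf_state: dict[int, np.ndarray] = {}
        for v, part in leaf_partials.items():
            if np.array_equal(part.sum(axis=1), np.ones(self.n_patterns)):
                self.leaf_state[v] = part.argmax(axis=1)

    # -- forward pass -------------------------------------------------------

    def _postorder(self, kernel, edge_lengths: np.ndarray, omega_class: int):
        """Partials, messages-to-parent, and cumulative log-scalers."""
        tree = self.tree
        n = tree.n_nodes
        L: list = [None] * n
        M: list = [None] * n  # message from node to its parent
        logS = [None] * n
        P: list = [None] * n
        for v in range(n):
            if not tree.children[v]:
                L[v] = self.leaf_partials[v]
                logS[v] = np.zeros(self.n_patterns)
            else:
                raw = None
                logs = np.zeros(self.n_patterns)
                for c in tree.children[v]:
                    raw = M[c] if raw is None else raw * M[c]
                    logs = logs + logS[c]
                sc = raw.max(axis=1)
                sc[sc <= 0.0] = 1.0
                L[v] = raw / sc[:, None]
                logS[v] = logs + np.log(sc)
            if v != tree.root:
                P[v] = kernel.transition(edge_lengths[v], omega_class)
                if v in self.leaf_state:
                    M[v] = P[v][:, self.leaf_state[v]].T
                else:
                    M[v] = L[v] @ P[v].T
        return L, M, logS, P

    def site_loglik_per_class(self, kernel, edge_lengths: np.ndarray) -> np.ndarray:
        """(n_classes, n_patterns) log-likelihoods, one row per omega class."""
        f = kernel.freqs
        out = np.empty((kernel.n_classes, self.n_patterns))
        for k in range(kernel.n_classes):
            L, _, logS, _ = self._postorder(kernel, edge_lengths, k)
            root_lik = L[self.tree.root] @ f
            out[k] = np.log(np.maximum(root_lik, 1e-300)) + logS[self.tree.root]
        return out

    def site_loglik(self, kernel, edge_lengths: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood under the omega mixture."""
        per_class = self.site_loglik_per_class(kernel, edge_lengths)
        logw = np.log(np.maximum(kernel.class_weights, 1e-300))
        return logsumexp(per_class + logw[:, None], axis=0)

    def loglik(self, kernel, edge_lengths: np.ndarray) -> float:
        return float(self.site_loglik(kernel, edge_lengths) @ self.weights)

    # -- forward + branch gradient ------------------------------------------

    def loglik_and_branch_grad(
        self, kernel, edge_lengths: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Total lnL, d lnL / d t for every edge, and per-pattern lnL.

        One post-order and one pre-order pass per mixture class.  For edge e
        (above node v) and class k,

            d L_site,k / d t_e = sum_ij G_v[i] (Q_k P_k(t_e))_ij L_v[j]

        where G_v is the likelihood of the rest of the tree indexed by the
        parent-end state of e, and L_v the subtree partial at v.
        """
        tree = self.tree
        n = tree.n_nodes
        logw = np.log(np.maximum(kernel.class_weights, 1e-300))
        n_cl = kernel.n_classes

        site_log_k = np.empty((n_cl, self.n_patterns))
        # per class: per-edge derivative values and their log-scalers
        dvals = np.zeros((n_cl, n, self.n_patterns))
        dlogs = np.zeros((n_cl, n, self.n_patterns))

        for k in range(n_cl):
            L, M, logS, P = self._postorder(kernel, edge_lengths, k)
            root = tree.root
            root_lik = np.maximum(L[root] @ kernel.freqs, 1e-300)
            site_log_k[k] = np.log(root_lik) + logS[root]

            # pre-order: F[v] = rest-of-tree partial indexed by v's state
            F: list = [None] * n
            logF = [None] * n
            F[root] = np.broadcast_to(kernel.freqs, (self.n_patterns, self.n_states))
            logF[root] = np.zeros(self.n_patterns)
            for v in range(n - 1, -1, -1):
                ch = tree.children[v]
                if not ch:
                    continue
                # leave-one-out products of children messages
                m = len(ch)
                prefix = [None] * (m + 1)
                suffix = [None] * (m + 1)
                prefix[0] = np.ones((self.n_patterns, self.n_states))
                for i, c in enumerate(ch):
                    prefix[i + 1] = prefix[i] * M[c]
                suffix[m] = np.ones((self.n_patterns, self.n_states))
                for i in range(m - 1, -1, -1):
                    suffix[i] = suffix[i + 1] * M[ch[i]]
                for i, c in enumerate(ch):
                    G = F[v] * prefix[i] * suffix[i + 1]
                    logG = logF[v] + sum(
                        (logS[cc] for j, cc in enumerate(ch) if j != i),
                        np.zeros(self.n_patterns),
                    )
                    dP = kernel.dtransition(edge_lengths[c], k)
                    if c in self.leaf_state:
                        dvals[k, c] = (G * dP[:, self.leaf_state[c]].T).sum(axis=1)
                    else:
                        dvals[k, c] = ((G @ dP) * L[c]).sum(axis=1)
                    dlogs[k, c] = logG + logS[c]
                    if tree.children[c]:  # F is only consumed below c
                        Fc = G @ P[c]
                        sc = Fc.max(axis=1)
                        sc[sc <= 0.0] = 1.0
                        F[c] = Fc / sc[:, None]
                        logF[c] = logG + np.log(sc)

        site_lnL = logsumexp(site_log_k + logw[:, None], axis=0)
        total = float(site_lnL @ self.weights)

        # combine class derivatives:  d lnL_s / d t_e
        #   = sum_k w_k d_e,k exp(c_e,k) / exp(site_lnL_s)
        # computed in log magnitude to dodge overflow when a derivative is
        # tiny but its scaler is large (or vice versa)
        grad = np.zeros(tree.n_edges)
        for e in range(tree.n_edges):
            num = np.zeros(self.n_patterns)
            for k in range(n_cl):
                d = dvals[k, e]
                nz = d != 0.0
                if not nz.any():
                    continue
                mag = (
                    logw[k]
                    + dlogs[k, e][nz]
                    - site_lnL[nz]
                    + np.log(np.abs(d[nz]))
                )
                num[nz] += np.sign(d[nz]) * np.exp(np.minimum(mag, 700.0))
            grad[e] = float(num @ self.weights)
        return total, grad, site_lnL


def make_codon_engine(aln, tree: PhyloTree) -> TreeLikelihood:
    """Build a pattern-compressed codon likelihood engine."""
    leaf_map = tree.match_taxa(aln.taxa)
    pat_sites, pat_weights, _ = aln.compress_patterns()
    n_states = aln.code.n_sense
    leaf_partials = {}
    for leaf, row in leaf_map.items():
        arr = np.empty((len(pat_sites), n_states))
        for pi, si in enumerate(pat_sites):
            arr[pi] = aln.leaf_partial(row, int(si))
        leaf_partials[leaf] = arr
    return TreeLikelihood(tree, leaf_partials, pat_weights)


def expand_site_loglik(aln, pattern_site_lnL: np.ndarray) -> np.ndarray:
    """Map per-pattern log-likelihoods back to per-site order."""
    _, _, site_to_pat = aln.compress_patterns()
    return pattern_site_lnL[site_to_pat]
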