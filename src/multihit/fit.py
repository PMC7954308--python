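"""Maximum-likelihood fitting of the multiple-hit codon model hierarchy.

Fitting proceeds in the order of increasing model complexity.  Branch
lengths and nucleotide exchangeabilities are initialized from a nucleotide
GTR fit; each codon model is then optimized by box-constrained L-BFGS-B
over all free parameters jointly, warm-started from the previous model's
maximum with the newly freed multiple-hit rate starting at its zero
boundary.  Because L-BFGS-B never moves to a worse point than its start,
this construction guarantees the nesting chain
``lnL(1H) <= lnL(2H) <= lnL(3HSI), lnL(3H) <= lnL(3H+)`` exactly.

Branch-length derivatives are analytic (one pre-order pass); derivatives
with respect to the handful of global rate parameters use forward
differences.  Positional frequencies (CF3x4) are estimated once per
alignment from counts and held fixed across all five models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .frequencies import PositionalFrequencies, estimate_frequencies
from .likelihood import TreeLikelihood, make_codon_engine
from .ratematrix import (
    FREE_THETA_SLOTS,
    MODEL_SPECS,
    ModelParams,
    ModelSpec,
    ReversibleKernel,
    TransitionKernel,
)
from .tree import PhyloTree

logger = logging.getLogger(__name__)

MIN_BRANCH = 1e-7
MAX_BRANCH = 25.0
MAX_THETA = 100.0
MIN_THETA = 1e-4
MIN_OMEGA = 1e-8
MAX_OMEGA = 1e4
MAX_MH_RATE = 1e3


@dataclass
class FitSettings:
    """Optimizer controls.

    ``maxiter`` caps L-BFGS-B iterations; ``ftol`` is the relative
    reduction threshold passed to L-BFGS-B.  ``n_omega_classes`` is the
    number of bins D of the dN/dS general discrete distribution (D = 3
    default; D = 1 collapses to a single shared omega).
    """

    n_omega_classes: int = 3
    frequency_method: str = "cf3x4"
    maxiter: int = 500
    ftol: float = 1e-10
    gtol: float = 1e-7
    fd_step: float = 1e-6


@dataclass
class FitResult:
    """Outcome of fitting one model.

    ``site_lnL`` is per alignment site (pattern-expanded) and sums to
    ``lnL``; ``site_lnL_by_class`` is (D, n_sites) and supports the
    empirical-Bayes omega-class assignment used in ancestral
    reconstruction.
    """

    spec: ModelSpec
    params: ModelParams
    lnL: float
    site_lnL: np.ndarray
    site_lnL_by_class: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "lnL": self.lnL,
            "params": self.params.to_dict(),
            "site_lnL": self.site_lnL.tolist(),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iter),
        }


# ---------------------------------------------------------------------------
# GTR initialization
# ---------------------------------------------------------------------------

_NT_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _nucleotide_engine(aln: CodonAlignment, tree: PhyloTree) -> tuple:
    """4-state pruning engine over the nucleotide columns of the alignment."""
    leaf_map = tree.match_taxa(aln.taxa)
    seqs = aln.raw_sequences
    n_cols = len(seqs[0])
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    rows = {leaf: seqs[row] for leaf, row in leaf_map.items()}
    # pattern compression on columns
    cols = list(zip(*[rows[leaf] for leaf in sorted(rows)]))
    uniq: dict[tuple, int] = {}
    weights: list[int] = []
    kept: list[tuple] = []
    for col in cols:
        if col in uniq:
            weights[uniq[col]] += 1
        else:
            uniq[col] = len(kept)
            kept.append(col)
            weights.append(1)
    leaf_order = sorted(rows)
    partials = {}
    freqs = np.zeros(4)
    for li, leaf in enumerate(leaf_order):
        arr = np.zeros((len(kept), 4))
        for pi, col in enumerate(kept):
            ch = col[li]
            allowed = _NT_AMBIG.get(ch, "")
            if not allowed:
                arr[pi] = 1.0
            else:
                for a in allowed:
                    arr[pi, nt_index[a]] = 1.0
                if len(allowed) == 1:
                    freqs[nt_index[allowed]] += weights[pi]
        partials[leaf] = arr
    if freqs.sum() == 0:
        freqs = np.ones(4)
    freqs = (freqs + 0.5) / (freqs + 0.5).sum()
    engine = TreeLikelihood(tree, partials, np.asarray(weights, dtype=float))
    return engine, freqs


def _gtr_kernel(theta: np.ndarray, freqs: np.ndarray) -> ReversibleKernel:
    """Normalized 4-state GTR matrix q_xy = theta_xy pi_y."""
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    Q = np.zeros((4, 4))
    for k, (x, y) in enumerate(pairs):
        Q[x, y] = theta[k] * freqs[y]
        Q[y, x] = theta[k] * freqs[x]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = -(freqs * np.diag(Q)).sum()
    return ReversibleKernel([Q / flux], freqs, np.ones(1))


def fit_gtr_init(
    aln: CodonAlignment,
    tree: PhyloTree,
    settings: FitSettings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleotide GTR fit for starting values.

    Returns ``(theta, codon_branch_lengths)`` with theta in the AC AG AT CG
    CT GT order (AG fixed at 1) and branch lengths converted to expected
    substitutions per *codon* site (3x the nucleotide estimate).
    """
    settings = settings or FitSettings()
    engine, freqs = _nucleotide_engine(aln, tree)
    n_edges = tree.n_edges
    t0 = np.maximum(tree.branch_lengths() / 3.0, 1e-4)
    x0 = np.concatenate([np.ones(5), t0])
    bounds = [(MIN_THETA, MAX_THETA)] * 5 + [(1e-8, MAX_BRANCH)] * n_edges

    def unpack_theta(x5: np.ndarray) -> np.ndarray:
        th = np.empty(6)
        th[list(FREE_THETA_SLOTS)] = x5
        th[1] = 1.0  # AG
        return th

    def fun(x: np.ndarray):
        kernel = _gtr_kernel(unpack_theta(x[:5]), freqs)
        el = np.append(x[5:], 0.0)
        lnL, bgrad, _ = engine.loglik_and_branch_grad(kernel, el)
        g = np.empty_like(x)
        g[5:] = -bgrad
        for i in range(5):
            h = settings.fd_step * max(abs(x[i]), 1e-2)
            xp = x.copy()
            xp[i] += h
            kp = _gtr_kernel(unpack_theta(xp[:5]), freqs)
            g[i] = -(engine.loglik(kp, el) - lnL) / h
        return -lnL, g

    # starting values only: moderate effort suffices
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 60, "ftol": 1e-9, "maxcor": 20})
    theta = unpack_theta(res.x[:5])
    codon_lengths = 3.0 * res.x[5:]
    return theta, codon_lengths


# ---------------------------------------------------------------------------
# Codon model fitting
# ---------------------------------------------------------------------------


class _Parameterization:
    """Maps between the free-parameter vector and ModelParams.

    Vector layout: [log theta (5), log omega (D), weight logits (D-1),
    mh rates (0-3 per spec), log branch lengths (n_edges)].
    Theta, omega and branch lengths are optimized on the log scale for
    conditioning; the multiple-hit rates stay on their natural linear
    scale so a warm start can sit exactly on the zero boundary of a newly
    freed rate.
    """

    def __init__(self, spec: ModelSpec, D: int, n_edges: int,
                 pi: PositionalFrequencies):
        self.spec = spec
        self.D = D
        self.n_edges = n_edges
        self.pi = pi
        self.mh_names: list[str] = []
        if spec.delta_free:
            self.mh_names.append("delta")
        if spec.psi_s_mode == "free":
            self.mh_names.append("psi_s")
        if spec.psi_free:
            self.mh_names.append("psi")
        self.n_global = 5 + D + (D - 1) + len(self.mh_names)

    def bounds(self) -> list[tuple[float, float]]:
        b = [(np.log(MIN_THETA), np.log(MAX_THETA))] * 5
        b += [(np.log(MIN_OMEGA), np.log(MAX_OMEGA))] * self.D
        b += [(-30.0, 30.0)] * (self.D - 1)
        b += [(0.0, MAX_MH_RATE)] * len(self.mh_names)
        b += [(np.log(MIN_BRANCH), np.log(MAX_BRANCH))] * self.n_edges
        return b

    def pack(self, params: ModelParams) -> np.ndarray:
        x = np.empty(self.n_global + self.n_edges)
        x[:5] = np.log(np.maximum(params.theta[list(FREE_THETA_SLOTS)],
                                  MIN_THETA))
        x[5 : 5 + self.D] = np.log(np.maximum(params.omega, MIN_OMEGA))
        w = np.maximum(params.weights, 1e-12)
        x[5 + self.D : 5 + 2 * self.D - 1] = np.log(w[:-1] / w[-1])
        off = 5 + 2 * self.D - 1
        for i, name in enumerate(self.mh_names):
            x[off + i] = getattr(params, name)
        x[self.n_global :] = np.log(
            np.maximum(params.branch_lengths, MIN_BRANCH)
        )
        return x

    def branch_lengths(self, x: np.ndarray) -> np.ndarray:
        return np.exp(x[self.n_global :])

    def unpack(self, x: np.ndarray) -> ModelParams:
        theta = np.empty(6)
        theta[list(FREE_THETA_SLOTS)] = np.exp(x[:5])
        theta[1] = 1.0
        omega = np.exp(x[5 : 5 + self.D])
        z = np.append(x[5 + self.D : 5 + 2 * self.D - 1], 0.0)
        z = z - z.max()
        w = np.exp(z)
        w /= w.sum()
        off = 5 + 2 * self.D - 1
        mh = {"delta": 0.0, "psi_s": 0.0, "psi": 0.0}
        for i, name in enumerate(self.mh_names):
            mh[name] = float(x[off + i])
        if self.spec.psi_s_mode == "tied":
            mh["psi_s"] = mh["psi"]
        return ModelParams(
            theta=theta,
            pi=self.pi,
            omega=omega,
            weights=w,
            delta=mh["delta"],
            psi_s=mh["psi_s"],
            psi=mh["psi"],
            branch_lengths=self.branch_lengths(x),
        )


def default_start(
    spec: ModelSpec,
    pi: PositionalFrequencies,
    theta: np.ndarray,
    branch_lengths: np.ndarray,
    D: int,
) -> ModelParams:
    """Fresh starting point given GTR estimates (no warm start available)."""
    if D == 1:
        omega = np.array([0.5])
        weights = np.array([1.0])
    else:
        omega = np.linspace(0.1, 1.0, D)
        weights = np.full(D, 1.0 / D)
    return ModelParams(
        theta=theta.copy(),
        pi=pi,
        omega=omega,
        weights=weights,
        delta=0.05 if spec.delta_free else 0.0,
        psi_s=0.05 if spec.psi_s_mode == "free" else 0.0,
        psi=0.05 if spec.psi_free else 0.0,
        branch_lengths=np.maximum(branch_lengths, 1e-4),
    )


def carry_over(params: ModelParams, spec: ModelSpec) -> ModelParams:
    """Adapt a simpler model's MLEs as the next model's starting point.

    Newly freed multiple-hit rates start at 0 (the boundary), so the warm
    start reproduces the simpler model's likelihood exactly.
    """
    new = replace(params, branch_lengths=params.branch_lengths.copy())
    if not spec.delta_free:
        new.delta = 0.0
    if spec.psi_s_mode == "zero":
        new.psi_s = 0.0
    if spec.psi_s_mode == "tied":
        new.psi_s = new.psi
    if not spec.psi_free:
        new.psi = 0.0
    return new


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: ModelSpec | str,
    init: Optional[ModelParams] = None,
    settings: FitSettings | None = None,
    pi: Optional[PositionalFrequencies] = None,
    engine: Optional[TreeLikelihood] = None,
) -> FitResult:
    """Fit one model of the hierarchy by direct likelihood maximization."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    settings = settings or FitSettings()
    code = aln.code
    if engine is None:
        engine = make_codon_engine(aln, tree)
    if pi is None:
        pi = (init.pi if init is not None
              else estimate_frequencies(aln, code, settings.frequency_method))
    if init is None:
        theta0, bl0 = fit_gtr_init(aln, tree, settings)
        init = default_start(spec, pi, theta0, bl0, settings.n_omega_classes)
    else:
        init = carry_over(init, spec)
    D = init.n_classes
    par = _Parameterization(spec, D, tree.n_edges, pi)
    x0 = par.pack(init)
    bounds = par.bounds()
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    n_glob = par.n_global
    eval_count = [0]

    def loglik_only(x: np.ndarray) -> float:
        params = par.unpack(x)
        kernel = TransitionKernel(params, spec, code)
        el = np.append(par.branch_lengths(x), 0.0)
        eval_count[0] += 1
        return engine.loglik(kernel, el)

    def fun(x: np.ndarray):
        params = par.unpack(x)
        kernel = TransitionKernel(params, spec, code)
        lengths = par.branch_lengths(x)
        el = np.append(lengths, 0.0)
        lnL, bgrad, _ = engine.loglik_and_branch_grad(kernel, el)
        eval_count[0] += 1
        g = np.empty_like(x)
        # chain rule for the log-branch-length parameterization
        g[n_glob:] = -bgrad[: tree.n_edges] * lengths
        for i in range(n_glob):
            h = settings.fd_step * max(abs(x[i]), 1e-3)
            if x[i] + h > bounds[i][1]:
                h = -h
            xp = x.copy()
            xp[i] += h
            g[i] = -(loglik_only(xp) - lnL) / h
        return -lnL, g

    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": settings.maxiter,
            "ftol": settings.ftol,
            "gtol": settings.gtol,
            "maxcor": 25,
        },
    )
    params = par.unpack(res.x).sorted_omega()
    kernel = TransitionKernel(params, spec, code)
    el = np.append(par.branch_lengths(res.x), 0.0)
    site_by_class = engine.site_loglik_per_class(kernel, el)
    logw = np.log(np.maximum(params.weights, 1e-300))
    from scipy.special import logsumexp

    pat_lnL = logsumexp(site_by_class + logw[:, None], axis=0)
    lnL = float(pat_lnL @ engine.weights)
    _, _, site_to_pat = aln.compress_patterns()
    logger.debug(
        "fit %s: lnL=%.6f iters=%d evals=%d %s",
        spec.name, lnL, res.nit, eval_count[0], res.message,
    )
    return FitResult(
        spec=spec,
        params=params,
        lnL=lnL,
        site_lnL=pat_lnL[site_to_pat],
        site_lnL_by_class=site_by_class[:, site_to_pat],
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )


def fit_hierarchy(
    aln: CodonAlignment,
    tree: PhyloTree,
    models: tuple[str, ...] = ("1H", "2H", "3HSI", "3H", "3H+"),
    settings: FitSettings | None = None,
) -> dict[str, FitResult]:
    """Fit the requested models in order of increasing complexity.

    Warm-start chain: GTR -> 1H -> 2H -> {3HSI, 3H} -> 3H+, where 3H+
    starts from the better of 3HSI and 3H so the nesting inequalities hold
    by construction.
    """
    settings = settings or FitSettings()
    code = aln.code
    pi = estimate_frequencies(aln, code, settings.frequency_method)
    engine = make_codon_engine(aln, tree)
    results: dict[str, FitResult] = {}

    warm: dict[str, Optional[ModelParams]] = {}
    order = [m for m in ("1H", "2H", "3HSI", "3H", "3H+") if m in models]
    prev_chain = {"1H": None, "2H": "1H", "3HSI": "2H", "3H": "2H", "3H+": None}
    for name in order:
        if name == "3H+":
            donors = [results[m] for m in ("3HSI", "3H") if m in results]
            if not donors:
                donors = [results[m] for m in ("2H", "1H") if m in results]
            init = max(donors, key=lambda r: r.lnL).params if donors else None
        else:
            prev = prev_chain[name]
            init = results[prev].params if prev and prev in results else None
        results[name] = fit_model(
            aln, tree, MODEL_SPECS[name], init=init,
            settings=settings, pi=pi, engine=engine,
        )
    return results
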