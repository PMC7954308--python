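"""Instantaneous rate matrices for the multiple-hit codon model hierarchy.

The most general model (3H+) assigns every ordered pair of distinct sense
codons i -> j a rate built from six classes::

    1H synonymous        theta_xy * pi_y
    1H non-synonymous    omega_k * theta_xy * pi_y
    2H synonymous        delta * prod_2 (theta * pi)
    2H non-synonymous    delta * omega_k * prod_2 (theta * pi)
    3H synonymous        psi_s * prod_3 (theta * pi)
    3H non-synonymous    psi * omega_k * prod_3 (theta * pi)

where the product runs over the changed nucleotide positions, ``theta_xy``
is the symmetric nucleotide exchangeability for the change at that position
(theta_AG fixed at 1 for identifiability) and ``pi_y`` the target-nucleotide
frequency at that codon position.  ``omega_k`` is the dN/dS ratio of mixture
class k (a D-bin general discrete distribution across sites).  The simpler
models fix ``delta`` (2H), ``psi_s`` (synonymous 3H) and ``psi``
(non-synonymous 3H) to zero or tie them per :data:`MODEL_SPECS`.

The process is time-reversible with respect to the stop-excluded product
codon distribution: ``f_i q_ij = f_j q_ji`` holds for every parameter value
because theta is symmetric and the pi factors of the unchanged positions
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import scipy.linalg

from .frequencies import NT_INDEX, PositionalFrequencies, codon_frequencies
from .genetic_code import GeneticCode, classify_substitution, load_code

# order of the 6 symmetric nucleotide exchangeabilities
THETA_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
THETA_SLOT = {p: k for k, p in enumerate(THETA_PAIRS)}
THETA_SLOT.update({(b, a): k for (a, b), k in list(THETA_SLOT.items())})
AG_SLOT = THETA_SLOT[("A", "G")]
FREE_THETA_SLOTS = tuple(k for k in range(6) if k != AG_SLOT)


@dataclass(frozen=True)
class ModelSpec:
    """Which multiple-hit rates are free under one model of the hierarchy.

    ``psi_s_mode`` is one of ``"zero"``, ``"free"`` or ``"tied"`` (tied
    means psi_s is constrained equal to psi, as in the 3H model).
    """

    name: str
    delta_free: bool
    psi_s_mode: str
    psi_free: bool

    @property
    def n_mh_free(self) -> int:
        """Number of free multiple-hit rate parameters."""
        return (
            int(self.delta_free)
            + int(self.psi_s_mode == "free")
            + int(self.psi_free)
        )

    def nests_in(self, other: "ModelSpec") -> bool:
        """True if every parameter free here is free (or tied-free) in other."""
        order = {"1H": 0, "2H": 1, "3HSI": 2, "3H": 2.5, "3H+": 3}
        if self.name == "3HSI" and other.name == "3H":
            return False
        if self.name == "3H" and other.name == "3HSI":
            return False
        return order[self.name] <= order[other.name]


MODEL_SPECS: dict[str, ModelSpec] = {
    "1H": ModelSpec("1H", delta_free=False, psi_s_mode="zero", psi_free=False),
    "2H": ModelSpec("2H", delta_free=True, psi_s_mode="zero", psi_free=False),
    "3HSI": ModelSpec("3HSI", delta_free=True, psi_s_mode="free", psi_free=False),
    "3H": ModelSpec("3H", delta_free=True, psi_s_mode="tied", psi_free=True),
    "3H+": ModelSpec("3H+", delta_free=True, psi_s_mode="free", psi_free=True),
}

MODEL_ORDER = ("1H", "2H", "3HSI", "3H", "3H+")


@dataclass
class ModelParams:
    """Free parameters of one model in the hierarchy.

    Attributes
    ----------
    theta : ndarray, shape (6,)
        Symmetric nucleotide exchangeabilities in the order AC, AG, AT, CG,
        CT, GT; ``theta[AG] == 1`` by convention.
    pi : PositionalFrequencies
        Position-specific nucleotide frequencies (held fixed during fits).
    omega : ndarray, shape (D,)
        dN/dS value of each mixture class, ascending.
    weights : ndarray, shape (D,)
        Mixture weights, summing to 1.
    delta, psi_s, psi : float
        Multiple-hit rates relative to the synonymous single-hit baseline.
    branch_lengths : ndarray or None
        Expected substitutions per codon site per branch (edge order of the
        tree the params were fitted on).
    """

    theta: np.ndarray
    pi: PositionalFrequencies
    omega: np.ndarray
    weights: np.ndarray
    delta: float = 0.0
    psi_s: float = 0.0
    psi: float = 0.0
    branch_lengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.theta.shape != (6,):
            raise ValueError("theta must have 6 entries (AC AG AT CG CT GT)")
        if self.omega.shape != self.weights.shape:
            raise ValueError("omega and weights must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if min(self.delta, self.psi_s, self.psi) < 0 or np.any(self.omega < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.omega)

    def validate_against(self, spec: ModelSpec) -> None:
        """Check that rates fixed to zero / tied under ``spec`` are respected."""
        if not spec.delta_free and self.delta != 0.0:
            raise ValueError(f"{spec.name}: delta must be 0")
        if spec.psi_s_mode == "zero" and self.psi_s != 0.0:
            raise ValueError(f"{spec.name}: psi_s must be 0")
        if spec.psi_s_mode == "tied" and self.psi_s != self.psi:
            raise ValueError(f"{spec.name}: psi_s must equal psi")
        if not spec.psi_free and self.psi != 0.0:
            raise ValueError(f"{spec.name}: psi must be 0")

    def sorted_omega(self) -> "ModelParams":
        """Relabel mixture classes so omega is ascending (lnL-invariant)."""
        order = np.argsort(self.omega)
        return replace(self, omega=self.omega[order], weights=self.weights[order])

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "pi": self.pi.pi.tolist(),
            "pi_method": self.pi.method,
            "omega": self.omega.tolist(),
            "weights": self.weights.tolist(),
            "delta": self.delta,
            "psi_s": self.psi_s,
            "psi": self.psi,
            "branch_lengths": None
            if self.branch_lengths is None
            else np.asarray(self.branch_lengths).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            theta=np.array(d["theta"]),
            pi=PositionalFrequencies(
                pi=np.array(d["pi"]), method=d.get("pi_method", "cf3x4")
            ),
            omega=np.array(d["omega"]),
            weights=np.array(d["weights"]),
            delta=d.get("delta", 0.0),
            psi_s=d.get("psi_s", 0.0),
            psi=d.get("psi", 0.0),
            branch_lengths=None
            if d.get("branch_lengths") is None
            else np.array(d["branch_lengths"]),
        )


@dataclass(frozen=True)
class RateMatrix:
    """A rate matrix over sense codons for one omega class."""

    Q: np.ndarray
    scale: float  # expected substitutions per unit time before normalization


@lru_cache(maxsize=8)
def _pair_structure(table_id: int):
    """Precomputed index arrays describing every ordered sense-codon pair."""
    code = load_code(table_id)
    sense = code.sense_codons
    n = len(sense)
    I, J, NCH, SYN = [], [], [], []
    TSLOT = []  # (npairs, 3) theta slot per changed position, -1 padding
    PPOS = []  # codon position of each change
    PNT = []  # target nucleotide index of each change
    for a, ci in enumerate(sense):
        for b, cj in enumerate(sense):
            if a == b:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            cls = classify_substitution(ci, cj, code)
            I.append(a)
            J.append(b)
            NCH.append(cls.n_changes)
            SYN.append(cls.synonymous)
            tslot = [THETA_SLOT[(ci[p], cj[p])] for p in diffs]
            ppos = list(diffs)
            pnt = [NT_INDEX[cj[p]] for p in diffs]
            while len(tslot) < 3:
                tslot.append(-1)
                ppos.append(-1)
                pnt.append(-1)
            TSLOT.append(tslot)
            PPOS.append(ppos)
            PNT.append(pnt)
    return (
        n,
        np.array(I),
        np.array(J),
        np.array(NCH),
        np.array(SYN, dtype=bool),
        np.array(TSLOT),
        np.array(PPOS),
        np.array(PNT),
    )


def _base_factors(params: ModelParams, code: GeneticCode) -> tuple:
    """Theta*pi product over changed positions, for every ordered pair."""
    n, I, J, NCH, SYN, TSLOT, PPOS, PNT = _pair_structure(code.table_id)
    base = np.ones(len(I))
    for k in range(3):
        mask = NCH > k
        base[mask] *= (
            params.theta[TSLOT[mask, k]]
            * params.pi.pi[PPOS[mask, k], PNT[mask, k]]
        )
    return n, I, J, NCH, SYN, base


def build_rate_matrix(
    params: ModelParams,
    spec: ModelSpec,
    omega_class: int,
    code: GeneticCode,
    normalized: bool = False,
) -> RateMatrix:
    """Build the rate matrix for one omega class under one model spec.

    The returned matrix is unnormalized (``scale`` records its expected
    flux under the codon equilibrium distribution) unless ``normalized``.
    """
    params.validate_against(spec)
    n, I, J, NCH, SYN, base = _base_factors(params, code)
    mult = np.ones(len(I))
    mult[NCH == 2] = params.delta
    mult[(NCH == 3) & SYN] = params.psi_s
    mult[(NCH == 3) & ~SYN] = params.psi
    mult[~SYN] *= params.omega[omega_class]
    Q = np.zeros((n, n))
    Q[I, J] = base * mult
    np.fill_diagonal(Q, -Q.sum(axis=1))
    f = codon_frequencies(params.pi, code)
    scale = float(-(f * np.diag(Q)).sum())
    if normalized:
        if scale <= 0:
            raise ValueError("degenerate model: zero total substitution rate")
        Q = Q / scale
    return RateMatrix(Q=Q, scale=scale)


def normalize_matrices(
    matrices: list[RateMatrix], weights: np.ndarray, freqs: np.ndarray
) -> tuple[list[np.ndarray], float]:
    """Scale all class matrices by the common mixture-expected flux.

    After scaling, one unit of branch length equals one expected
    substitution per codon site under the full mixture model.
    """
    weights = np.asarray(weights, dtype=float)
    s = float(
        sum(
            w * -(freqs * np.diag(m.Q)).sum()
            for w, m in zip(weights, matrices)
        )
    )
    if s <= 0:
        raise ValueError("degenerate model: zero total substitution rate")
    return [m.Q / s for m in matrices], s


class ReversibleKernel:
    """Eigendecomposed reversible rate matrices for fast P(t) evaluation.

    Exploits time-reversibility: ``B = diag(f)^{1/2} Q diag(f)^{-1/2}`` is
    symmetric, so ``P(t) = D^{-1/2} V exp(L t) V' D^{1/2}`` with a real
    orthogonal eigenbasis.  Holds one matrix per mixture class.
    """

    def __init__(self, Q_list: list[np.ndarray], freqs: np.ndarray,
                 class_weights: np.ndarray):
        self.Q = list(Q_list)
        self.freqs = np.asarray(freqs, dtype=float)
        self.class_weights = np.asarray(class_weights, dtype=float)
        sq = np.sqrt(self.freqs)
        self._eig = []
        for Q in self.Q:
            B = sq[:, None] * Q / sq[None, :]
            w, V = scipy.linalg.eigh((B + B.T) / 2.0)
            left = V / sq[:, None]
            right = V.T * sq[None, :]
            self._eig.append((w, left, right))

    @property
    def n_classes(self) -> int:
        return len(self.Q)

    def transition(self, t: float, omega_class: int) -> np.ndarray:
        """P(t) = exp(Q_k t), rows summing to 1."""
        w, left, right = self._eig[omega_class]
        P = (left * np.exp(w * t)[None, :]) @ right
        np.clip(P, 0.0, None, out=P)
        return P

    def dtransition(self, t: float, omega_class: int) -> np.ndarray:
        """d/dt exp(Q_k t) = Q_k exp(Q_k t)."""
        w, left, right = self._eig[omega_class]
        return (left * (w * np.exp(w * t))[None, :]) @ right


class TransitionKernel(ReversibleKernel):
    """Kernel for one codon model: builds, normalizes and decomposes the
    per-omega-class matrices from a :class:`ModelParams`."""

    def __init__(self, params: ModelParams, spec: ModelSpec, code: GeneticCode):
        self.code = code
        self.params = params
        self.spec = spec
        freqs = codon_frequencies(params.pi, code)
        mats = [
            build_rate_matrix(params, spec, k, code)
            for k in range(params.n_classes)
        ]
        Q_norm, self.scale = normalize_matrices(mats, params.weights, freqs)
        super().__init__(Q_norm, freqs, params.weights)
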