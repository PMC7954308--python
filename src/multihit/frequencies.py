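"""Codon-position-specific nucleotide frequencies (F3x4 and CF3x4).

The equilibrium codon distribution of the model is a product of three
position-specific nucleotide distributions, renormalized over sense codons.
Plain F3x4 uses the observed per-position nucleotide proportions directly,
which is biased because excluding stop codons distorts the marginals of the
renormalized product.  CF3x4 corrects for this: it searches for positional
frequencies ``pi*`` such that the marginals of the stop-excluded codon
distribution implied by ``pi*`` match the observed proportions.  With 9 free
parameters matching 9 free observed proportions the system is generically
exactly identified and the residual vanishes to numerical precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .genetic_code import NUCLEOTIDES, GeneticCode

logger = logging.getLogger(__name__)

NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class PositionalFrequencies:
    """A 3x4 matrix of nucleotide frequencies, one row per codon position."""

    pi: np.ndarray  # shape (3, 4), rows sum to 1
    method: str = "f3x4"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (3, 4):
            raise ValueError("pi must be 3x4")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of pi must sum to 1")
        if np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("pi entries must lie in (0, 1)")
        object.__setattr__(self, "pi", pi)


def codon_frequencies(pos: PositionalFrequencies, code: GeneticCode) -> np.ndarray:
    """Equilibrium distribution over sense codons implied by ``pos``.

    ``f[c] ∝ pi[0][c0] * pi[1][c1] * pi[2][c2]``, renormalized so stop
    codons carry no mass.
    """
    f = np.array(
        [
            pos.pi[0, NT_INDEX[c[0]]]
            * pos.pi[1, NT_INDEX[c[1]]]
            * pos.pi[2, NT_INDEX[c[2]]]
            for c in code.sense_codons
        ]
    )
    return f / f.sum()


def implied_marginals(pos: PositionalFrequencies, code: GeneticCode) -> np.ndarray:
    """Per-position nucleotide marginals of the sense-codon distribution."""
    f = codon_frequencies(pos, code)
    marg = np.zeros((3, 4))
    for c, fc in zip(code.sense_codons, f):
        for p in range(3):
            marg[p, NT_INDEX[c[p]]] += fc
    return marg


def observed_position_counts(aln) -> np.ndarray:
    """Tally unambiguous nucleotides per codon position over an alignment.

    Ambiguity codes and gaps are excluded.  Accepts a
    :class:`~multihit.alignment.CodonAlignment` or any iterable of DNA
    strings whose length is a multiple of 3.
    """
    seqs = getattr(aln, "raw_sequences", None)
    if seqs is None:
        seqs = list(aln)
    if not seqs:
        raise ValueError("empty alignment")
    counts = np.zeros((3, 4))
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        for i, ch in enumerate(s):
            j = NT_INDEX.get(ch)
            if j is not None:
                counts[i % 3, j] += 1
    return counts


def f3x4(counts: np.ndarray) -> PositionalFrequencies:
    """Row-normalized positional counts, floored away from exact zeros."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("every codon position needs at least one observation")
    # tiny pseudocount keeps unobserved nucleotides at positive frequency
    counts = counts + 0.5
    pi = counts / counts.sum(axis=1, keepdims=True)
    return PositionalFrequencies(pi=pi, method="f3x4")


def _logits_to_pi(x: np.ndarray) -> np.ndarray:
    z = np.zeros((3, 4))
    z[:, :3] = x.reshape(3, 3)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cf3x4(counts: np.ndarray, code: GeneticCode) -> PositionalFrequencies:
    """Corrected F3x4 positional frequencies.

    Finds ``pi*`` minimizing the squared deviation between observed
    per-position proportions and the positional marginals of the
    stop-excluded codon distribution implied by ``pi*``.  Falls back to
    plain F3x4 (with a warning) if the optimizer fails to drive the
    L-infinity residual below 1e-6.
    """
    counts = np.asarray(counts, dtype=float)
    start = f3x4(counts)
    observed = start.pi  # pseudocounted observed proportions
    if not code.stop_codons:
        # no stop-exclusion distortion: CF3x4 coincides with F3x4
        return PositionalFrequencies(pi=observed, method="cf3x4")

    def objective(x: np.ndarray) -> float:
        pos = PositionalFrequencies(pi=_logits_to_pi(x), method="cf3x4")
        return float(((implied_marginals(pos, code) - observed) ** 2).sum())

    x0 = np.log(observed[:, :3] / observed[:, 3:4]).ravel()
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12})
    pos = PositionalFrequencies(pi=_logits_to_pi(res.x), method="cf3x4")
    resid = np.abs(implied_marginals(pos, code) - observed).max()
    if resid > 1e-6:
        warnings.warn(
            f"CF3x4 optimization did not converge (residual {resid:.2e}); "
            "falling back to F3x4",
            RuntimeWarning,
        )
        logger.warning("CF3x4 non-convergence, residual %.3e", resid)
        return start
    return pos


def estimate_frequencies(
    aln, code: GeneticCode, method: str = "cf3x4"
) -> PositionalFrequencies:
    """Estimate positional frequencies from an alignment."""
    counts = observed_position_counts(aln)
    if method == "cf3x4":
        return cf3x4(counts, code)
    if method == "f3x4":
        return f3x4(counts)
    raise ValueError(f"unknown frequency estimator: {method!r}")
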