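"""Genetic codes, substitution classes, and synonymous codon islands.

A codon substitution i -> j is classified by how many nucleotide positions
change (1, 2, or 3) and whether the encoded amino acid is preserved.  The
six resulting classes are the structural skeleton of the multiple-hit model
hierarchy: single-hit (1H) changes carry the baseline rate, double-hit (2H)
changes are scaled by ``delta``, and triple-hit (3H) changes by ``psi``
(non-synonymous) or ``psi_s`` (synonymous).

Synonymous *islands* are groups of synonymous codons that are mutually
reachable by single synonymous nucleotide steps.  In the universal code the
only amino acid with more than one island is serine (TCN and AGY): a
synonymous change between the two islands requires at least two simultaneous
nucleotide changes.  Islands are computed from the code itself (connected
components of the Hamming-distance-1 graph within each amino acid's codon
set), so non-standard codes with island structure in other amino acids are
handled automatically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))


class UnsupportedCodeError(ValueError):
    """Raised for translation-table ids not present in the NCBI registry."""


class InvalidCodonPairError(ValueError):
    """Raised when a codon pair cannot be classified (identical or stop)."""


def hamming(codon_i: str, codon_j: str) -> int:
    """Number of nucleotide positions at which two codons differ."""
    return sum(a != b for a, b in zip(codon_i, codon_j))


@dataclass(frozen=True)
class SubstitutionClass:
    """One of the six rate classes of the model hierarchy.

    Attributes
    ----------
    n_changes : int
        Number of nucleotide positions changed (1, 2, or 3).
    synonymous : bool
        True if the amino acid is unchanged.
    island_jump : bool
        True if the change is synonymous, involves >= 2 nucleotides, and the
        two codons lie in different synonymous islands of the amino acid.
        ``island_jump`` implies ``synonymous``.
    """

    n_changes: int
    synonymous: bool
    island_jump: bool = False

    def __post_init__(self) -> None:
        if self.island_jump and not self.synonymous:
            raise ValueError("island_jump implies synonymous")
        if self.n_changes not in (1, 2, 3):
            raise ValueError("n_changes must be 1, 2 or 3")

    @property
    def label(self) -> str:
        tag = f"{self.n_changes}H"
        kind = "synonymous" if self.synonymous else "non-synonymous"
        return f"{tag} {kind}" + (" island" if self.island_jump else "")


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its sense-codon set and island structure.

    Parameters
    ----------
    table_id : int
        NCBI translation-table number (1 = universal, 2 = vertebrate
        mitochondrial, ...).
    codon_to_aa : dict
        Map from each of the 64 codons to a one-letter amino acid, or ``"*"``
        for stop codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)
    islands: tuple[frozenset[str], ...] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != "*")
        stops = tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == "*")
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "islands", self._compute_islands())
        # index lookup for fast classification
        object.__setattr__(
            self, "_codon_index", {c: k for k, c in enumerate(sense)}
        )
        object.__setattr__(
            self,
            "_island_of",
            {c: i for i, isl in enumerate(self.islands) for c in isl},
        )

    def _compute_islands(self) -> tuple[frozenset[str], ...]:
        """Connected components of the synonymous single-step graph.

        Within each amino acid's codon set, codons at Hamming distance 1 are
        joined; each connected component is one island.
        """
        by_aa: dict[str, list[str]] = {}
        for c in ALL_CODONS:
            aa = self.codon_to_aa[c]
            if aa != "*":
                by_aa.setdefault(aa, []).append(c)
        islands: list[frozenset[str]] = []
        for codons in by_aa.values():
            unvisited = set(codons)
            while unvisited:
                seed = min(unvisited)
                component = {seed}
                frontier = [seed]
                while frontier:
                    cur = frontier.pop()
                    for other in list(unvisited - component):
                        if hamming(cur, other) == 1:
                            component.add(other)
                            frontier.append(other)
                unvisited -= component
                islands.append(frozenset(component))
        islands.sort(key=min)
        return tuple(islands)

    # -- queries -----------------------------------------------------------

    def index(self, codon: str) -> int:
        """Index of ``codon`` within ``sense_codons``."""
        return self._codon_index[codon]

    def is_sense(self, codon: str) -> bool:
        return codon in self._codon_index

    def islands_for(self, aa: str) -> tuple[frozenset[str], ...]:
        """All islands of codons encoding amino acid ``aa``."""
        return tuple(
            isl for isl in self.islands if self.codon_to_aa[min(isl)] == aa
        )

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)


@lru_cache(maxsize=None)
def load_code(table_id: int) -> GeneticCode:
    """Load a genetic code by NCBI translation-table number.

    Raises
    ------
    UnsupportedCodeError
        If ``table_id`` is not a known NCBI table.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except KeyError as exc:
        raise UnsupportedCodeError(
            f"unsupported NCBI translation table: {table_id!r}"
        ) from exc
    codon_to_aa = {c: "*" for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    # forward_table omits stops; make sure all 64 codons are covered
    assert len(codon_to_aa) == 64
    return GeneticCode(table_id=int(table_id), codon_to_aa=dict(codon_to_aa))


def classify_substitution(
    codon_i: str, codon_j: str, code: GeneticCode
) -> SubstitutionClass:
    """Classify the substitution ``codon_i -> codon_j`` under ``code``.

    Raises
    ------
    InvalidCodonPairError
        If the codons are identical or either is a stop codon.
    """
    if codon_i == codon_j:
        raise InvalidCodonPairError(f"identical codons: {codon_i}")
    if not code.is_sense(codon_i) or not code.is_sense(codon_j):
        raise InvalidCodonPairError(
            f"stop or invalid codon in pair {codon_i}->{codon_j}"
        )
    n = hamming(codon_i, codon_j)
    syn = code.codon_to_aa[codon_i] == code.codon_to_aa[codon_j]
    jump = bool(
        syn and n >= 2 and code._island_of[codon_i] != code._island_of[codon_j]
    )
    return SubstitutionClass(n_changes=n, synonymous=syn, island_jump=jump)


def count_substitution_classes(code: GeneticCode) -> dict[tuple[int, bool], int]:
    """Count ordered pairs of distinct sense codons in each of the 6 classes.

    Returns a dict keyed by ``(n_changes, synonymous)``; values over all six
    keys sum to ``n_sense * (n_sense - 1)``.
    """
    counts = {(n, s): 0 for n in (1, 2, 3) for s in (True, False)}
    for ci, cj in itertools.permutations(code.sense_codons, 2):
        cls = classify_substitution(ci, cj, code)
        counts[(cls.n_changes, cls.synonymous)] += 1
    return counts


def normalize_codon(codon: str) -> str:
    """Canonicalize a codon string: uppercase, RNA U mapped to DNA T."""
    return codon.upper().replace("U", "T")
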