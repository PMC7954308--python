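"""In-frame codon alignments with ambiguity and missing-data handling.

Each column of a :class:`CodonAlignment` holds, per taxon, either a single
sense-codon index, a set of compatible sense codons (IUPAC ambiguity), or
missing data (gaps, ``NNN``, or stop codons when ``allow_stops`` is on).
Missing and ambiguous states enter the likelihood as partial indicator
vectors, following the usual phylogenetic convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .genetic_code import GeneticCode, normalize_codon

MISSING = -1
AMBIGUOUS = -2

_NT_SETS = {k.upper(): set(v.upper()) for k, v in ambiguous_dna_values.items()}
_NT_SETS["U"] = {"T"}
_NT_SETS["-"] = set()
_NT_SETS["."] = set()
_NT_SETS["?"] = set("ACGT")


class StopCodonError(ValueError):
    """An observed in-frame stop codon (pass ``allow_stops`` to mask them)."""


class FrameError(ValueError):
    """Sequence length not divisible by 3, or unequal lengths."""


def _codon_state(codon: str, code: GeneticCode, allow_stops: bool,
                 taxon: str, site: int):
    """Resolve a 3-character string to a state: index, bool mask, or MISSING."""
    codon = normalize_codon(codon)
    if codon in ("---", "...",):
        return MISSING
    sets = []
    for ch in codon:
        s = _NT_SETS.get(ch)
        if s is None:
            raise ValueError(
                f"invalid character {ch!r} in {taxon} codon site {site + 1}"
            )
        if not s:  # partial gap: treat whole codon as missing
            return MISSING
        sets.append(s)
    if all(len(s) == 1 for s in sets):
        resolved = "".join(next(iter(s)) for s in sets)
        if code.is_sense(resolved):
            return code.index(resolved)
        if allow_stops:
            return MISSING
        raise StopCodonError(
            f"stop codon {resolved} in {taxon} at codon site {site + 1}; "
            "use allow_stops to mask stop codons as missing"
        )
    mask = np.zeros(code.n_sense, dtype=bool)
    for a in sets[0]:
        for b in sets[1]:
            for c in sets[2]:
                cod = a + b + c
                if code.is_sense(cod):
                    mask[code.index(cod)] = True
    if mask.all() or not mask.any():
        return MISSING
    return mask


@dataclass
class CodonAlignment:
    """Column-indexed codon states for a set of taxa.

    Attributes
    ----------
    taxa : list of str
    states : ndarray of int, shape (n_taxa, n_sites)
        Sense-codon index, or MISSING (-1), or AMBIGUOUS (-2) with the
        boolean mask stored in ``ambiguity``.
    code : GeneticCode
    """

    taxa: list[str]
    states: np.ndarray
    code: GeneticCode
    ambiguity: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    raw_sequences: list[str] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_sequences(
        cls,
        names: list[str],
        seqs: list[str],
        code: GeneticCode,
        allow_stops: bool = False,
    ) -> "CodonAlignment":
        if not names:
            raise ValueError("empty alignment")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise FrameError("sequences have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not divisible by 3")
        n_sites = length // 3
        states = np.empty((len(names), n_sites), dtype=np.int64)
        ambiguity: dict[tuple[int, int], np.ndarray] = {}
        norm_seqs = []
        for ti, (name, seq) in enumerate(zip(names, seqs)):
            seq = normalize_codon(seq)
            norm_seqs.append(seq)
            for si in range(n_sites):
                st = _codon_state(seq[3 * si : 3 * si + 3], code, allow_stops,
                                  name, si)
                if isinstance(st, np.ndarray):
                    states[ti, si] = AMBIGUOUS
                    ambiguity[(ti, si)] = st
                else:
                    states[ti, si] = st
        return cls(
            taxa=list(names),
            states=states,
            code=code,
            ambiguity=ambiguity,
            raw_sequences=norm_seqs,
        )

    # -- likelihood support -------------------------------------------------

    def leaf_partial(self, taxon_idx: int, site_idx: int) -> np.ndarray:
        """Indicator vector over sense codons for one cell."""
        s = self.states[taxon_idx, site_idx]
        if s >= 0:
            v = np.zeros(self.code.n_sense)
            v[s] = 1.0
            return v
        if s == MISSING:
            return np.ones(self.code.n_sense)
        return self.ambiguity[(taxon_idx, site_idx)].astype(float)

    def compress_patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique site patterns with multiplicities.

        Returns ``(pattern_states, weights, site_to_pattern)`` where
        ``pattern_states`` has shape (n_taxa, n_patterns).  Columns with
        ambiguity codes are kept as singleton patterns keyed by content.
        """
        keys: dict[tuple, int] = {}
        pat_cols: list[np.ndarray] = []
        weights: list[int] = []
        site_to_pat = np.empty(self.n_sites, dtype=np.int64)
        for si in range(self.n_sites):
            col = self.states[:, si]
            amb_part = tuple(
                (ti, self.ambiguity[(ti, si)].tobytes())
                for ti in range(self.n_taxa)
                if col[ti] == AMBIGUOUS
            )
            key = (col.tobytes(), amb_part)
            if key in keys:
                pi = keys[key]
                weights[pi] += 1
            else:
                pi = len(pat_cols)
                keys[key] = pi
                pat_cols.append(si)
                weights.append(1)
            site_to_pat[si] = pi
        return (
            np.array(pat_cols, dtype=np.int64),
            np.array(weights, dtype=float),
            site_to_pat,
        )

    def to_fasta(self, path: str | os.PathLike) -> None:
        """Write (unambiguous states only; missing rendered as ---)."""
        inv = self.code.sense_codons
        with open(path, "w") as fh:
            for ti, name in enumerate(self.taxa):
                chunks = []
                for si in range(self.n_sites):
                    s = self.states[ti, si]
                    if s >= 0:
                        chunks.append(inv[s])
                    elif self.raw_sequences:
                        chunks.append(self.raw_sequences[ti][3 * si : 3 * si + 3])
                    else:
                        chunks.append("---")
                fh.write(f">{name}\n{''.join(chunks)}\n")


def read_alignment(
    path: str | os.PathLike,
    code: GeneticCode,
    fmt: str = "auto",
    allow_stops: bool = False,
) -> CodonAlignment:
    """Read a FASTA or relaxed-PHYLIP protein-coding alignment.

    ``fmt='auto'`` sniffs the first non-blank character ('>' means FASTA).
    """
    if fmt == "auto":
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    fmt = "fasta" if line.lstrip()[0] == ">" else "phylip"
                    break
            else:
                raise ValueError(f"empty file: {path}")
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        names = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif fmt == "phylip":
        names, seqs = _read_relaxed_phylip(path)
    else:
        raise ValueError(f"unknown alignment format: {fmt!r}")
    if not names:
        raise ValueError(f"no sequences found in {path}")
    return CodonAlignment.from_sequences(names, seqs, code, allow_stops=allow_stops)


def _read_relaxed_phylip(path) -> tuple[list[str], list[str]]:
    """Sequential relaxed PHYLIP: header 'ntax nchar', then name + sequence
    (whitespace anywhere in the sequence, wrapping allowed)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 2:
        raise ValueError("truncated PHYLIP file")
    ntax, nchar = int(tokens[0]), int(tokens[1])
    names, seqs = [], []
    pos = 2
    for _ in range(ntax):
        if pos >= len(tokens):
            raise ValueError("PHYLIP file ended before all taxa were read")
        names.append(tokens[pos])
        pos += 1
        chunks: list[str] = []
        total = 0
        while total < nchar:
            if pos >= len(tokens):
                raise ValueError(f"sequence for {names[-1]} shorter than {nchar}")
            chunks.append(tokens[pos])
            total += len(tokens[pos])
            pos += 1
        seq = "".join(chunks)
        if len(seq) != nchar:
            raise ValueError(f"sequence for {names[-1]} has length {len(seq)}")
        seqs.append(seq)
    return names, seqs
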