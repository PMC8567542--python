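"""The standard genetic code, translation and back-translation combinatorics.

Codons are plain 3-character DNA strings (``A/C/G/T``; RNA ``U`` is
normalized to ``T`` on input).  Amino acids are single-letter codes with
``'*'`` for stop.  The total order on codons used everywhere for
deterministic tie-breaking is lexicographic with ``A < C < G < T``, i.e.
ordinary string order on the DNA spelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from importlib import resources
from typing import Iterable, Mapping

from .errors import (
    AlphabetError,
    FrameError,
    InputError,
    PrematureStopError,
)

DNA_BASES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

__all__ = [
    "DNA_BASES",
    "AMINO_ACIDS",
    "STOP",
    "normalize_codon",
    "validate_protein",
    "CodingSequence",
    "GeneticCode",
]


def normalize_codon(codon: str) -> str:
    """Return *codon* upper-cased with RNA ``U`` mapped to DNA ``T``.

    Raises :class:`AlphabetError` if the result is not three characters
    over ``{A,C,G,T}``.
    """
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or not set(c) <= DNA_BASES:
        raise AlphabetError(f"not a valid codon: {codon!r}")
    return c


def validate_protein(sequence: str | Iterable[str]) -> str:
    """Validate and normalize a protein sequence.

    Accepts the 20 standard single-letter codes; ``'*'`` is permitted only
    as an optional final residue (an explicit stop request).  Returns the
    upper-cased string.
    """
    seq = "".join(sequence).strip().upper()
    if not seq:
        raise InputError("empty protein sequence")
    for pos, aa in enumerate(seq):
        if aa == STOP:
            if pos != len(seq) - 1:
                raise PrematureStopError(
                    f"'*' at position {pos + 1} is not terminal"
                )
        elif aa not in AMINO_ACIDS:
            raise AlphabetError(
                f"unknown amino-acid symbol {aa!r} at position {pos + 1}"
            )
    return seq


@dataclass(frozen=True)
class CodingSequence:
    """An ordered list of codons; ``dna`` is their concatenation."""

    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "codons", tuple(normalize_codon(c) for c in self.codons)
        )
        if not self.codons:
            raise InputError("empty coding sequence")

    @classmethod
    def from_dna(cls, dna: str) -> "CodingSequence":
        s = dna.strip().upper().replace("U", "T")
        if not s:
            raise InputError("empty coding sequence")
        if bad := set(s) - DNA_BASES:
            raise AlphabetError(f"non-ACGT characters in DNA: {sorted(bad)}")
        if len(s) % 3:
            raise FrameError(f"length {len(s)} is not a multiple of 3")
        return cls(tuple(s[i : i + 3] for i in range(0, len(s), 3)))

    @property
    def dna(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:
        return len(self.codons)

    def __add__(self, other: "CodingSequence") -> "CodingSequence":
        return CodingSequence(self.codons + other.codons)


class GeneticCode:
    """A total map between the 64 codons and amino acids (stops = ``'*'``).

    Parameters
    ----------
    codon_to_aa
        Mapping from all 64 codons to single-letter amino acids.  The
        standard nuclear code (NCBI translation table 1) is available via
        :meth:`standard`; alternative tables may be supplied here.
    """

    def __init__(self, codon_to_aa: Mapping[str, str]) -> None:
        table = {normalize_codon(c): aa.upper() for c, aa in codon_to_aa.items()}
        if len(table) != 64:
            raise InputError(
                f"genetic code must map all 64 codons, got {len(table)}"
            )
        if bad := set(table.values()) - AMINO_ACIDS - {STOP}:
            raise AlphabetError(f"unknown amino acids in code: {sorted(bad)}")
        self.codon_to_aa: dict[str, str] = dict(sorted(table.items()))
        aa_to_codons: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            aa_to_codons.setdefault(aa, []).append(codon)
        # codons arrive sorted, so each synonymous list is sorted too
        self.aa_to_codons: dict[str, tuple[str, ...]] = {
            aa: tuple(cs) for aa, cs in aa_to_codons.items()
        }

    _standard: "GeneticCode | None" = None

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code, loaded from the shipped table."""
        if cls._standard is None:
            text = (
                resources.files("codonopt.data")
                .joinpath("standard_genetic_code.tsv")
                .read_text()
            )
            table = {}
            for line in text.splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                codon, aa = line.split("\t")
                table[codon] = aa
            cls._standard = cls(table)
        return cls._standard

    # -- queries -----------------------------------------------------------

    def synonymous_codons(self, aa: str) -> tuple[str, ...]:
        """The sorted synonymous codon set of *aa* (``'*'`` for stops)."""
        aa = aa.upper()
        if aa not in self.aa_to_codons:
            raise AlphabetError(f"unknown amino-acid symbol {aa!r}")
        return self.aa_to_codons[aa]

    def amino_acid(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    def translate(self, cds: CodingSequence | str) -> str:
        """Decode a coding sequence to its protein.

        A stop codon is accepted only at the final position, where it is
        rendered as a trailing ``'*'``.
        """
        if isinstance(cds, str):
            cds = CodingSequence.from_dna(cds)
        residues = []
        for pos, codon in enumerate(cds.codons):
            aa = self.codon_to_aa[codon]
            if aa == STOP and pos != len(cds) - 1:
                raise PrematureStopError(
                    f"stop codon {codon} at codon position {pos + 1}"
                )
            residues.append(aa)
        return "".join(residues)

    def candidate_combination_count(self, protein: str) -> int:
        """Number of distinct coding sequences for *protein*.

        The product of the synonymous-set sizes over all residues, computed
        in exact integer arithmetic (it grows exponentially with length —
        already past a million at twenty residues of two-fold degeneracy).
        """
        protein = validate_protein(protein)
        return reduce(
            lambda n, aa: n * len(self.synonymous_codons(aa)), protein, 1
        )
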