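"""Codon-pair context score tables.

A score table assigns a real score to every ordered (5', 3') codon pair.
The sign carries the biology: negative = rejected context, positive =
preferred, zero = no significance.  Discretized tables (all scores in
{-2,-1,0,1,2}) are the common case for published context maps; the engine
nevertheless works with arbitrary real scores.

The built-in default table is derived from the four context rules observed
in the Pichia pastoris codon-pair map: pairs whose 5' codon ends in T are
rejected before a 3' codon starting with A and favored before one starting
with G; pairs whose 5' codon ends in C are rejected before G and favored
before A.  All other juxtapositions are neutral.
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

from .errors import InputError, ParameterError, TableError
from .genetic_code import CodingSequence, normalize_codon

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)

REJECTED, PREFERRED, NEUTRAL = "rejected", "preferred", "neutral"

__all__ = [
    "ALL_CODONS",
    "REJECTED",
    "PREFERRED",
    "NEUTRAL",
    "classify_score",
    "CodonPairScoreTable",
]


def classify_score(score: float) -> str:
    """Map a score to its context class by sign."""
    if score < 0:
        return REJECTED
    if score > 0:
        return PREFERRED
    return NEUTRAL


class CodonPairScoreTable:
    """A total map from the 4096 ordered codon pairs to real scores."""

    def __init__(
        self,
        scores: dict[tuple[str, str], float],
        provenance: str = "unspecified",
    ) -> None:
        norm: dict[tuple[str, str], float] = {}
        for (c5, c3), s in scores.items():
            norm[(normalize_codon(c5), normalize_codon(c3))] = s
        missing = 4096 - len(norm)
        if missing:
            raise TableError(f"score table incomplete: {missing} pairs missing")
        self.scores = norm
        self.provenance = provenance
        self.discretized = all(
            float(s).is_integer() and -2 <= s <= 2 for s in norm.values()
        )
        if self.discretized:
            self.scores = {k: int(v) for k, v in norm.items()}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_rules(
        cls, reject_magnitude: float = 1.0, favor_magnitude: float = 1.0
    ) -> "CodonPairScoreTable":
        """Build the default rule-derived table.

        Each rule constrains one base of each codon (the 5' wobble base and
        the 3' first base), so each rule class covers 16 x 16 = 256 pairs:
        512 rejected, 512 preferred and 3072 neutral cells in total.
        """
        if reject_magnitude <= 0 or favor_magnitude <= 0:
            raise ParameterError("rule magnitudes must be positive")
        scores: dict[tuple[str, str], float] = {}
        for c5 in ALL_CODONS:
            for c3 in ALL_CODONS:
                end, start = c5[2], c3[0]
                if (end, start) in (("T", "A"), ("C", "G")):
                    s = -reject_magnitude
                elif (end, start) in (("T", "G"), ("C", "A")):
                    s = favor_magnitude
                else:
                    s = 0.0
                scores[(c5, c3)] = s
        return cls(scores, provenance="rule-derived default (stops scored by the same rules)")

    @classmethod
    def from_tsv(
        cls,
        source: str | TextIO,
        dialect: str = "auto",
        sparse: bool = False,
        provenance: str | None = None,
    ) -> "CodonPairScoreTable":
        """Load a table from TSV.

        Two dialects are supported.  ``long-triples``: a header line
        ``codon5<TAB>codon3<TAB>score`` followed by one row per pair.
        ``dense-matrix``: an empty first cell, 64 codon column headers, then
        64 rows each led by the 5' codon.  ``auto`` sniffs the header.  RNA
        spellings are normalized.  By default every one of the 4096 pairs
        must be present; with ``sparse=True`` unlisted pairs score 0.
        """
        if isinstance(source, str):
            label = provenance or f"loaded: {source}"
            with open(source, "r", encoding="utf-8", newline="") as fh:
                text = fh.read()
        else:
            label = provenance or "loaded: <stream>"
            text = source.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise TableError("empty score-table file")
        header = lines[0].split("\t")
        if dialect == "auto":
            dialect = "dense-matrix" if header[0].strip() == "" else "long-triples"
        scores: dict[tuple[str, str], float] = {}

        def put(c5: str, c3: str, raw: str) -> None:
            try:
                val = float(raw)
            except ValueError as exc:
                raise TableError(f"non-numeric score {raw!r} for {c5}-{c3}") from exc
            key = (normalize_codon(c5), normalize_codon(c3))
            if key in scores and scores[key] != val:
                raise TableError(
                    f"conflicting duplicate scores for pair {key[0]}-{key[1]}"
                )
            scores[key] = val

        if dialect == "long-triples":
            start = 1 if header[:2] == ["codon5", "codon3"] else 0
            for ln in lines[start:]:
                fields = ln.split("\t")
                if len(fields) != 3:
                    raise TableError(f"malformed long-triples row: {ln!r}")
                put(*fields)
        elif dialect == "dense-matrix":
            cols = [normalize_codon(c) for c in header[1:]]
            if len(cols) != 64:
                raise TableError(f"dense matrix needs 64 columns, got {len(cols)}")
            for ln in lines[1:]:
                fields = ln.split("\t")
                if len(fields) != 65:
                    raise TableError(f"malformed dense-matrix row: {ln!r}")
                c5 = fields[0]
                for c3, raw in zip(cols, fields[1:]):
                    put(c5, c3, raw)
        else:
            raise ParameterError(f"unknown dialect {dialect!r}")

        if sparse:
            for c5 in ALL_CODONS:
                for c3 in ALL_CODONS:
                    scores.setdefault((c5, c3), 0.0)
        return cls(scores, provenance=label)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, target: str | TextIO, dialect: str = "long-triples") -> None:
        """Write the table; formats are bit-exact inverses of the loaders."""
        buf = io.StringIO()
        if dialect == "long-triples":
            buf.write("codon5\tcodon3\tscore\n")
            for c5 in ALL_CODONS:
                for c3 in ALL_CODONS:
                    buf.write(f"{c5}\t{c3}\t{self.scores[(c5, c3)]:g}\n")
        elif dialect == "dense-matrix":
            buf.write("\t" + "\t".join(ALL_CODONS) + "\n")
            for c5 in ALL_CODONS:
                row = "\t".join(f"{self.scores[(c5, c3)]:g}" for c3 in ALL_CODONS)
                buf.write(f"{c5}\t{row}\n")
        else:
            raise ParameterError(f"unknown dialect {dialect!r}")
        if isinstance(target, str):
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(buf.getvalue())
        else:
            target.write(buf.getvalue())

    # -- evaluation --------------------------------------------------------

    def score_pair(self, five_prime: str, three_prime: str) -> float:
        return self.scores[(normalize_codon(five_prime), normalize_codon(three_prime))]

    def classify_pair(self, five_prime: str, three_prime: str) -> str:
        return classify_score(self.score_pair(five_prime, three_prime))

    def score_sequence(
        self, cds: CodingSequence | Iterable[str] | str
    ) -> tuple[float, list[float]]:
        """Total context score of a coding sequence and its junction scores.

        The total is the sum over the n-1 adjacent ordered pairs; a
        single-codon sequence scores 0 with no junctions.
        """
        if isinstance(cds, str):
            cds = CodingSequence.from_dna(cds)
        codons = [normalize_codon(c) for c in (cds.codons if isinstance(cds, CodingSequence) else cds)]
        if not codons:
            raise InputError("empty coding sequence")
        junctions = [
            self.scores[(a, b)] for a, b in zip(codons, codons[1:])
        ]
        return sum(junctions), junctions

    def negated(self) -> "CodonPairScoreTable":
        return CodonPairScoreTable(
            {k: -v for k, v in self.scores.items()},
            provenance=f"negated({self.provenance})",
        )

    def class_census(self) -> dict[str, int]:
        """Counts of rejected / preferred / neutral cells over all 4096."""
        census = {REJECTED: 0, PREFERRED: 0, NEUTRAL: 0}
        for s in self.scores.values():
            census[classify_score(s)] += 1
        return census
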