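"""Codon-usage-bias (CUB) optimization: the classical comparator.

Single-codon optimization replaces every residue's codon with the host's
preferred (most frequent) synonymous codon, independently of its
neighbours.  It is the one-codon-per-amino-acid strategy: the same codon is
always selected for a given amino acid, by construction.  The pair-context
total of the result can be evaluated under any score table for comparison
against the pair-context optimizer, which searches the same feasible set
and therefore always bounds it from above (mode "best") and below
(mode "worst").
"""

from __future__ import annotations

import io
import math
from typing import TextIO

from .dp_optimizer import OptimizationResult
from .errors import ParameterError, TableError
from .genetic_code import STOP, CodingSequence, GeneticCode, validate_protein
from .pair_scoring import ALL_CODONS, CodonPairScoreTable

__all__ = ["CodonUsageTable", "optimize_cub"]


class CodonUsageTable:
    """Relative synonymous codon frequencies for a host organism.

    Accepts raw counts or frequencies; values are normalized to fractions
    summing to 1 within each synonymous codon set.  Strict totality: all 64
    codons must be present unless ``sparse=True`` (absent codons get 0).
    """

    def __init__(
        self,
        usage: dict[str, float],
        code: GeneticCode | None = None,
        provenance: str = "unspecified",
        sparse: bool = False,
    ) -> None:
        code = code or GeneticCode.standard()
        self.code = code
        self.provenance = provenance
        raw = {c.upper().replace("U", "T"): float(v) for c, v in usage.items()}
        if any(v < 0 for v in raw.values()):
            raise TableError("negative codon frequency")
        missing = set(ALL_CODONS) - set(raw)
        if missing and not sparse:
            raise TableError(
                f"usage table incomplete: missing {sorted(missing)[:3]}"
                f"{'...' if len(missing) > 3 else ''} ({len(missing)} codons)"
            )
        for c in missing:
            raw[c] = 0.0
        self.fractions: dict[str, float] = {}
        for aa, codons in code.aa_to_codons.items():
            tot = sum(raw[c] for c in codons)
            for c in codons:
                # a fully unobserved synonymous set falls back to uniform
                self.fractions[c] = raw[c] / tot if tot > 0 else 1.0 / len(codons)

    @classmethod
    def uniform(cls, code: GeneticCode | None = None) -> "CodonUsageTable":
        return cls(
            {c: 1.0 for c in ALL_CODONS}, code=code, provenance="uniform"
        )

    @classmethod
    def from_tsv(
        cls,
        source: str | TextIO,
        code: GeneticCode | None = None,
        sparse: bool = False,
    ) -> "CodonUsageTable":
        """Load ``codon<TAB>frequency`` rows (counts work equally)."""
        if isinstance(source, str):
            label = f"loaded: {source}"
            with open(source, "r", encoding="utf-8", newline="") as fh:
                text = fh.read()
        else:
            label = "loaded: <stream>"
            text = source.read()
        usage: dict[str, float] = {}
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if fields[0].strip().lower() == "codon":
                continue
            if len(fields) != 2:
                raise TableError(f"malformed usage row: {ln!r}")
            try:
                usage[fields[0]] = float(fields[1])
            except ValueError as exc:
                raise TableError(f"non-numeric frequency in row {ln!r}") from exc
        return cls(usage, code=code, provenance=label, sparse=sparse)

    def to_tsv(self, target: str | TextIO) -> None:
        buf = io.StringIO()
        buf.write("codon\tfrequency\n")
        for c in ALL_CODONS:
            buf.write(f"{c}\t{self.fractions[c]:.6f}\n")
        if isinstance(target, str):
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(buf.getvalue())
        else:
            target.write(buf.getvalue())

    def preferred_codon(self, aa: str) -> str:
        """Arg-max frequency synonymous codon; ties break lexicographically."""
        codons = self.code.synonymous_codons(aa)
        return min(codons, key=lambda c: (-self.fractions[c], c))


def optimize_cub(
    protein: str,
    usage: CodonUsageTable,
    code: GeneticCode | None = None,
    append_stop: bool = False,
    pair_table: CodonPairScoreTable | None = None,
) -> OptimizationResult:
    """Back-translate *protein* choosing each residue's preferred codon.

    A pure per-residue map (permuting the protein permutes the codons
    identically).  When *pair_table* is given, the result's context score
    total and junction scores are evaluated under it for comparison with
    the pair-context modes; otherwise they are reported as NaN/empty.
    """
    code = code or GeneticCode.standard()
    if usage.code.codon_to_aa != code.codon_to_aa:
        raise ParameterError("usage table was built for a different genetic code")
    protein = validate_protein(protein)
    if append_stop and not protein.endswith(STOP):
        protein += STOP
    cds = CodingSequence(tuple(usage.preferred_codon(aa) for aa in protein))
    if pair_table is not None:
        total, junctions = pair_table.score_sequence(cds)
        provenance = pair_table.provenance
    else:
        total, junctions, provenance = math.nan, [], "no pair table supplied"
    return OptimizationResult(
        cds=cds,
        total_score=total,
        junction_scores=tuple(junctions),
        mode="cub",
        states_explored=len(cds),
        ties_encountered=0,
        table_provenance=provenance,
    )
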