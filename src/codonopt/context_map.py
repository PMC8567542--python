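"""Diagnostic reports for designed coding sequences.

Two views of a sequence's codon-pair context quality:

* the pair-context report classifies every adjacent codon pair as
  rejected / preferred / neutral (score sign) and lays the codons out
  row-major into a 16-column grid, each cell coloured by its context
  relative to its 5' neighbour -- red for rejected, green for preferred,
  black (plain) for neutral, with intensity tracking |score| when the
  table is discretized;
* the synonymous-usage report tallies, per amino acid occurring at least
  ``min_count`` times (default 10), how many distinct synonymous codons
  the sequence employs and how often each.  A usage-optimized sequence
  always shows exactly one codon per amino acid; a pair-context-optimized
  one typically varies them.

All coordinates in emitted TSVs are 1-based codon positions.
"""

from __future__ import annotations

import html as _html
import io
from dataclasses import dataclass
from typing import TextIO

from .errors import InputError
from .genetic_code import CodingSequence, GeneticCode
from .pair_scoring import (
    NEUTRAL,
    PREFERRED,
    REJECTED,
    CodonPairScoreTable,
    classify_score,
)

MAP_COLUMNS = 16

__all__ = [
    "JunctionRecord",
    "PairContextReport",
    "SynonymousUsageReport",
    "classify_sequence",
    "synonymous_usage",
    "render_text_map",
    "render_html_map",
]


@dataclass(frozen=True)
class JunctionRecord:
    """One adjacent ordered codon pair; position is the 1-based 3' codon index."""

    position: int
    codon5: str
    codon3: str
    score: float
    pair_class: str


@dataclass(frozen=True)
class PairContextReport:
    junctions: tuple[JunctionRecord, ...]
    counts: dict[str, int]
    total_score: float
    #: codons row-major in MAP_COLUMNS columns; each cell is
    #: (codon, class-or-None, score-or-None); the first codon has no class
    map_layout: tuple[tuple[tuple[str, str | None, float | None], ...], ...]
    table_provenance: str

    def to_junctions_tsv(self, target: str | TextIO) -> None:
        _write(target, self._junctions_text())

    def to_summary_tsv(self, target: str | TextIO) -> None:
        _write(target, self._summary_text())

    def _junctions_text(self) -> str:
        buf = io.StringIO()
        buf.write("# positions are 1-based codon indices (3' codon of the pair)\n")
        buf.write("pos\tcodon5\tcodon3\tscore\tclass\n")
        for j in self.junctions:
            buf.write(
                f"{j.position}\t{j.codon5}\t{j.codon3}\t{j.score:g}\t{j.pair_class}\n"
            )
        return buf.getvalue()

    def _summary_text(self) -> str:
        buf = io.StringIO()
        buf.write("class\tcount\n")
        for cls in (REJECTED, PREFERRED, NEUTRAL):
            buf.write(f"{cls}\t{self.counts[cls]}\n")
        return buf.getvalue()


@dataclass(frozen=True)
class SynonymousUsageReport:
    """Per-amino-acid codon tallies for residues above the count threshold."""

    min_count: int
    #: aa -> (occurrence count, {codon: tally}); only aa with count >= min_count
    entries: dict[str, tuple[int, dict[str, int]]]
    #: unfiltered tallies over the whole sequence
    all_tallies: dict[str, dict[str, int]]

    def distinct_codons(self, aa: str) -> int:
        return len(self.all_tallies.get(aa, {}))

    def to_tsv(self, target: str | TextIO) -> None:
        buf = io.StringIO()
        buf.write(f"# amino acids occurring >= {self.min_count} times\n")
        buf.write("aa\tcount\tcodon\ttally\n")
        for aa in sorted(self.entries):
            count, tallies = self.entries[aa]
            for codon in sorted(tallies):
                buf.write(f"{aa}\t{count}\t{codon}\t{tallies[codon]}\n")
        _write(target, buf.getvalue())


def _write(target: str | TextIO, text: str) -> None:
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        target.write(text)


def classify_sequence(
    cds: CodingSequence | str, table: CodonPairScoreTable
) -> PairContextReport:
    """Classify every junction of *cds* and build the 16-column context map.

    Class counts always sum to (codon count - 1); the first codon carries no
    class because it has no 5' neighbour.  The grid starts with the first
    codon in the upper-left cell and ends with the last (for a full design,
    the stop codon) in the final cell; the last row may be ragged.
    """
    if isinstance(cds, str):
        cds = CodingSequence.from_dna(cds)
    codons = cds.codons
    junctions = []
    counts = {REJECTED: 0, PREFERRED: 0, NEUTRAL: 0}
    cell_class: list[str | None] = [None]
    cell_score: list[float | None] = [None]
    for i, (a, b) in enumerate(zip(codons, codons[1:]), start=2):
        s = table.scores[(a, b)]
        cls = classify_score(s)
        counts[cls] += 1
        junctions.append(JunctionRecord(i, a, b, s, cls))
        cell_class.append(cls)
        cell_score.append(s)
    rows = []
    for i in range(0, len(codons), MAP_COLUMNS):
        rows.append(
            tuple(
                (codons[j], cell_class[j], cell_score[j])
                for j in range(i, min(i + MAP_COLUMNS, len(codons)))
            )
        )
    return PairContextReport(
        junctions=tuple(junctions),
        counts=counts,
        total_score=sum(j.score for j in junctions),
        map_layout=tuple(rows),
        table_provenance=table.provenance,
    )


def synonymous_usage(
    cds: CodingSequence | str,
    code: GeneticCode | None = None,
    min_count: int = 10,
) -> SynonymousUsageReport:
    """Tally synonymous-codon usage per amino acid in *cds*.

    Only amino acids occurring at least *min_count* times appear in
    ``entries`` (set ``min_count=1`` to report all); per-codon tallies
    always sum to the amino acid's occurrence count.
    """
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    if isinstance(cds, str):
        cds = CodingSequence.from_dna(cds)
    code = code or GeneticCode.standard()
    protein = code.translate(cds)  # raises on premature stop
    all_tallies: dict[str, dict[str, int]] = {}
    for aa, codon in zip(protein, cds.codons):
        all_tallies.setdefault(aa, {})
        all_tallies[aa][codon] = all_tallies[aa].get(codon, 0) + 1
    entries = {
        aa: (sum(t.values()), dict(t))
        for aa, t in all_tallies.items()
        if sum(t.values()) >= min_count
    }
    return SynonymousUsageReport(
        min_count=min_count, entries=entries, all_tallies=all_tallies
    )


_ANSI = {REJECTED: "\x1b[31m", PREFERRED: "\x1b[32m", None: "", NEUTRAL: ""}
_RESET = "\x1b[0m"


def render_text_map(report: PairContextReport, color: bool = False) -> str:
    """Plain-text grid; with ``color=True`` rejected/preferred cells are
    ANSI red/green, otherwise marked with ``-``/``+`` suffixes."""
    lines = []
    for row in report.map_layout:
        cells = []
        for codon, cls, _score in row:
            if color:
                pre = _ANSI[cls]
                cells.append(f"{pre}{codon}{_RESET if pre else ''}")
            else:
                mark = {REJECTED: "-", PREFERRED: "+"}.get(cls, " ")
                cells.append(f"{codon}{mark}")
        lines.append(" ".join(cells))
    return "\n".join(lines) + "\n"


def render_html_map(report: PairContextReport) -> str:
    """Minimal HTML table with the red/green/black convention; opacity
    encodes |score| for discretized tables (max magnitude 2)."""
    color = {REJECTED: "red", PREFERRED: "green", NEUTRAL: "black", None: "gray"}
    out = ["<table style='font-family:monospace;border-collapse:collapse'>"]
    for row in report.map_layout:
        out.append("<tr>")
        for codon, cls, score in row:
            opacity = ""
            if score is not None and cls != NEUTRAL:
                opacity = f";opacity:{min(abs(score) / 2.0, 1.0):.2f}"
            out.append(
                f"<td style='color:{color[cls]};padding:2px{opacity}'>"
                f"{_html.escape(codon)}</td>"
            )
        out.append("</tr>")
    out.append("</table>")
    return "".join(out)
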