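"""FASTA reading and writing (Biopython-backed)."""

from __future__ import annotations

import logging
from io import StringIO
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

log = logging.getLogger("codonopt")

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(source: str | TextIO) -> list[tuple[str, str]]:
    """Read FASTA records as ``(identifier, upper-case sequence)`` pairs.

    Case-insensitive on read; CRLF input parses identically to LF.
    Duplicate identifiers are suffix-deduplicated (``id.2``, ``id.3`` ...)
    with a warning.  An empty file is an error.
    """
    handle = open(source, "r", encoding="utf-8") if isinstance(source, str) else source
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
    finally:
        if isinstance(source, str):
            handle.close()
    if not records:
        raise InputError(f"no FASTA records in {source!r}")
    seen: dict[str, int] = {}
    out = []
    for ident, seq in records:
        seen[ident] = seen.get(ident, 0) + 1
        if seen[ident] > 1:
            log.warning("duplicate FASTA identifier %r; renaming", ident)
            ident = f"{ident}.{seen[ident]}"
        out.append((ident, seq))
    return out


def write_fasta(
    records: Iterable[tuple[str, str] | tuple[str, str, str]],
    target: str | TextIO,
    wrap: int = 60,
) -> None:
    """Write ``(id, seq)`` or ``(id, description, seq)`` records, wrapped."""
    seqrecords = []
    for rec in records:
        if len(rec) == 3:
            ident, desc, seq = rec
        else:
            ident, seq = rec
            desc = ""
        seqrecords.append(SeqRecord(Seq(seq.upper()), id=ident, description=desc))
    buf = StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=wrap)
    writer.write_file(seqrecords)
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    else:
        target.write(buf.getvalue())
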