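"""FASTQ input/output (Phred+33, gzip-aware) shared by the pipeline stages."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .qc import ReadRecord

__all__ = ["read_fastq", "write_fastq"]


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate FASTQ records as :class:`~tfy1h.qc.ReadRecord`."""
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                identifier=rec.description or rec.id,
                bases=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ; returns the number written.

    Records are written verbatim in input order so that a fixed simulation
    seed yields a byte-identical file.
    """
    n = 0
    with _open_text(path, "w") as handle:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            handle.write(f"@{rec.identifier}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n
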