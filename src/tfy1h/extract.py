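"""Insert recovery from amplicon reads by flanking-anchor matching.

Each read should contain the constant amplicon flanks around the random
insert.  The extractor looks, on the read and on its reverse complement, for
the ``anchor_len``-suffix of the upstream flank and the
``anchor_len``-prefix of the downstream flank — each allowed up to
``max_mismatch`` Hamming mismatches, no indels — separated by exactly k
bases.  The k bases between the anchors are the insert; a read yields an
insert only when that placement is unique and the insert is free of N calls.
Non-extractable reads are tallied under a reason code rather than treated as
errors:

``no_anchor``
    neither a valid anchor pair nor both anchors anywhere in the read;
``wrong_gap``
    both anchors were found but never at the exact k-base separation;
``ambiguous``
    more than one valid placement (or, in paired mode, discordant mates);
``contains_N``
    the placement is unique but the insert contains an undetermined base.

Successful inserts are collapsed into a k-mer count table, the package's
central container for enrichment and motif discovery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .library_model import AmpliconTemplate
from .qc import ReadRecord

__all__ = [
    "KmerTable",
    "ExtractionStats",
    "extract_insert",
    "extract_all",
    "unique_inserts",
]

REASONS = ("no_anchor", "ambiguous", "wrong_gap", "contains_N")


@dataclass
class KmerTable:
    """Counts over the 4**k insert space: the extracted-read tally."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for km, c in self.counts.items():
            if len(km) != self.k or any(b not in "ACGT" for b in km):
                raise ValueError(f"invalid k-mer key {km!r} for k={self.k}")
            if c <= 0:
                raise ValueError(f"non-positive count for {km!r}")

    @property
    def total(self) -> int:
        """Total extracted reads N (sum of counts)."""
        return sum(self.counts.values())

    @property
    def unique_count(self) -> int:
        return len(self.counts)

    @classmethod
    def from_inserts(cls, inserts: Iterable[str], k: int) -> "KmerTable":
        return cls(k=k, counts=dict(Counter(inserts)))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["kmer", "count"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerTable":
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
        if df.empty:
            raise ValueError(f"empty k-mer table: {path}")
        k = len(df["kmer"].iloc[0])
        return cls(k=k, counts=dict(zip(df["kmer"], df["count"])))

    def write_fasta(self, path: str | Path) -> None:
        """Unique inserts as FASTA (motif-discovery input)."""
        with open(path, "w") as handle:
            for i, km in enumerate(unique_inserts(self)):
                handle.write(f">insert_{i} count={self.counts[km]}\n{km}\n")


@dataclass
class ExtractionStats:
    extracted: int = 0
    no_anchor: int = 0
    ambiguous: int = 0
    wrong_gap: int = 0
    contains_N: int = 0

    @property
    def input_reads(self) -> int:
        return self.extracted + self.no_anchor + self.ambiguous + self.wrong_gap + self.contains_N

    @property
    def success_rate(self) -> float:
        n = self.input_reads
        return self.extracted / n if n else 0.0

    def as_dict(self) -> dict[str, int]:
        return {
            "extracted": self.extracted,
            "no_anchor": self.no_anchor,
            "ambiguous": self.ambiguous,
            "wrong_gap": self.wrong_gap,
            "contains_N": self.contains_N,
        }


def _hamming_le(a: str, b: str, budget: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def _anchor_hits(seq: str, anchor: str, max_mismatch: int) -> list[int]:
    """Start positions where ``anchor`` matches within the mismatch budget."""
    al = len(anchor)
    if max_mismatch == 0:
        hits, start = [], 0
        while True:
            i = seq.find(anchor, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1
    return [
        i
        for i in range(len(seq) - al + 1)
        if _hamming_le(seq[i : i + al], anchor, max_mismatch)
    ]


def extract_insert(
    read: ReadRecord | str,
    template: AmpliconTemplate,
    anchor_len: int = 12,
    max_mismatch: int = 1,
) -> tuple[str | None, str]:
    """Extract the insert from one read; returns (insert, reason).

    ``reason`` is ``"extracted"`` on success, else one of the codes in
    :data:`REASONS`.  Extraction is strand-invariant: the read and its
    reverse complement yield the same result.
    """
    if anchor_len > min(len(template.upstream_flank), len(template.downstream_flank)):
        raise ValueError("anchor_len exceeds a flank length")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = (read.bases if isinstance(read, ReadRecord) else read).upper()
    up = template.upstream_flank[-anchor_len:]
    down = template.downstream_flank[:anchor_len]
    k = template.n_region_len

    placements: list[str] = []
    saw_both_anchors = False
    rc = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    for strand_seq in (seq, rc):
        ups = _anchor_hits(strand_seq, up, max_mismatch)
        downs = _anchor_hits(strand_seq, down, max_mismatch)
        if ups and downs:
            saw_both_anchors = True
        down_set = set(downs)
        for i in ups:
            j = i + anchor_len + k
            if j in down_set:
                placements.append(strand_seq[i + anchor_len : j])
    if len(placements) == 1:
        insert = placements[0]
        if "N" in insert:
            return None, "contains_N"
        return insert, "extracted"
    if len(placements) > 1:
        return None, "ambiguous"
    return None, ("wrong_gap" if saw_both_anchors else "no_anchor")


def extract_all(
    reads: Iterable[ReadRecord],
    template: AmpliconTemplate,
    anchor_len: int = 12,
    max_mismatch: int = 1,
    paired: bool = False,
) -> tuple[KmerTable, ExtractionStats]:
    """Extract inserts from every read and tally them into a k-mer table.

    In paired mode ``reads`` is an iterable of (mate1, mate2) tuples; the
    mates are extracted independently, a concordant pair counts once, a
    discordant pair is discarded as ambiguous, and a pair in which only one
    mate yields an insert uses that insert.
    """
    stats = ExtractionStats()
    counts: Counter[str] = Counter()

    def tally(insert: str | None, reason: str) -> None:
        if insert is not None:
            counts[insert] += 1
            stats.extracted += 1
        else:
            setattr(stats, reason, getattr(stats, reason) + 1)

    if paired:
        for mate1, mate2 in reads:
            ins1, r1 = extract_insert(mate1, template, anchor_len, max_mismatch)
            ins2, r2 = extract_insert(mate2, template, anchor_len, max_mismatch)
            if ins1 is not None and ins2 is not None:
                if ins1 == ins2:
                    tally(ins1, "extracted")
                else:
                    tally(None, "ambiguous")
            elif ins1 is not None:
                tally(ins1, "extracted")
            elif ins2 is not None:
                tally(ins2, "extracted")
            else:
                # charge the pair to mate 1's failure reason
                tally(None, r1)
    else:
        for read in reads:
            tally(*extract_insert(read, template, anchor_len, max_mismatch))
    return KmerTable(k=template.n_region_len, counts=dict(counts)), stats


def unique_inserts(table: KmerTable) -> list[str]:
    """The table's distinct k-mers in lexicographic order (deterministic
    motif-discovery input)."""
    return sorted(table.counts)
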