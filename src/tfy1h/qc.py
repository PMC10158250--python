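"""Read quality control: whole-read filters producing the clean read set.

Three filters are applied in a fixed order, and each read is charged to the
first rule it violates:

1. adapter contamination — the read contains any supplied adapter sequence
   as an exact substring;
2. undetermined bases — the fraction of ``N`` calls strictly exceeds
   ``max_n_frac`` (default 5%);
3. low quality — the mean Phred score is <= ``min_mean_q`` (default 10);
   a per-base mode drops a read whose *minimum* quality is below the bar
   instead.

Reads that pass are kept unmodified; no trimming is performed, matching a
protocol that removes whole low-quality reads rather than clipping them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["ReadRecord", "QcStats", "filter_reads"]


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases (may contain N), Phred scores."""

    identifier: str
    bases: str
    qualities: list[int]

    def validate(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass
class QcStats:
    """Per-category read tallies; categories partition the input."""

    input_reads: int = 0
    kept_reads: int = 0
    dropped_adapter: int = 0
    dropped_n: int = 0
    dropped_quality: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_reads": self.input_reads,
            "kept_reads": self.kept_reads,
            "dropped_adapter": self.dropped_adapter,
            "dropped_n": self.dropped_n,
            "dropped_quality": self.dropped_quality,
        }

    def check(self) -> None:
        assert self.input_reads == (
            self.kept_reads + self.dropped_adapter + self.dropped_n + self.dropped_quality
        )


def filter_reads(
    reads: Iterable[ReadRecord],
    adapters: Sequence[str] = (),
    max_n_frac: float = 0.05,
    min_mean_q: float = 10.0,
    per_base: bool = False,
) -> tuple[list[ReadRecord], QcStats]:
    """Apply the whole-read filters; returns (kept reads, category tallies).

    ``per_base=True`` switches the quality rule from mean read quality to the
    minimum per-base quality.
    """
    adapters = [a.upper() for a in adapters]
    kept: list[ReadRecord] = []
    stats = QcStats()
    for read in reads:
        read.validate()
        stats.input_reads += 1
        bases = read.bases.upper()
        if any(adapter in bases for adapter in adapters):
            stats.dropped_adapter += 1
            continue
        if bases and bases.count("N") / len(bases) > max_n_frac:
            stats.dropped_n += 1
            continue
        q_stat = min(read.qualities, default=0) if per_base else read.mean_quality
        if q_stat <= min_mean_q:
            stats.dropped_quality += 1
            continue
        kept.append(read)
        stats.kept_reads += 1
    stats.check()
    return kept, stats
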