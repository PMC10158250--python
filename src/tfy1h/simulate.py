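"""Synthetic TF-centered one-hybrid experiments with full ground truth.

The simulator mirrors the three stochastic layers of the real screen:

1. **Library construction** — colonies receive inserts drawn i.i.d. uniformly
   from the 4**k insert space (the saturated-library design).
2. **Selection** — a colony survives the reporter selection iff its insert
   matches one of the planted binding patterns (exactly, or as a substring);
   non-matching colonies survive with a background false-positive probability,
   collapsing binding-strength gradation into a single rate.
3. **Sequencing** — each surviving colony contributes ``depth`` amplicon
   reads, emitted from a uniformly random strand with i.i.d. substitution
   errors and constant Phred qualities consistent with the error rate.

Every stage records ground truth (per-colony insert, matched and survived
flags, per-read source colony), so downstream extraction, enrichment and
motif discovery can be validated read-by-read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library_model import (
    AmpliconTemplate,
    DRE_CRT,
    GCC_BOX,
    IupacPattern,
    design_template,
    enumerate_inserts,
    iupac_match,
    iupac_search,
)
from .qc import ReadRecord

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "sample_prey_library",
    "apply_selection",
    "emit_reads",
    "run_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G on 0..3 codes


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults follow the real experiment's scale where stated — 150,000
    colonies over the 4**7 = 16,384 insert space, 150-bp reads — and sensible
    screen-like values where it is not: both canonical ERF elements planted as
    substring patterns, a 2% false-positive survival rate, 50 reads per
    surviving colony and a 0.1% per-base substitution error rate.
    """

    n_colonies: int = 150_000
    k: int = 7
    binding_patterns: tuple[IupacPattern, ...] = (GCC_BOX, DRE_CRT)
    match_mode: str = "substring"  # or "exact"
    fp_rate: float = 0.02
    depth: int = 50
    error_rate: float = 0.001
    read_len: int = 150
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError("fp_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.match_mode not in ("exact", "substring"):
            raise ValueError("match_mode must be 'exact' or 'substring'")
        self.binding_patterns = tuple(
            p if isinstance(p, IupacPattern) else IupacPattern(p)
            for p in self.binding_patterns
        )

    def as_json(self) -> str:
        cfg = {
            "n_colonies": self.n_colonies,
            "k": self.k,
            "binding_patterns": [str(p) for p in self.binding_patterns],
            "match_mode": self.match_mode,
            "fp_rate": self.fp_rate,
            "depth": self.depth,
            "error_rate": self.error_rate,
            "read_len": self.read_len,
            "paired": self.paired,
            "seed": self.seed,
        }
        return json.dumps(cfg, indent=2)


def sample_prey_library(n_colonies: int, k: int, seed: int) -> list[str]:
    """Draw ``n_colonies`` inserts i.i.d. uniformly over the 4**k space."""
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n_colonies, k), dtype=np.int8)
    chars = _BASES[codes]
    return [row.tobytes().decode() for row in chars]


def _matching_insert_set(
    k: int, patterns: Sequence[IupacPattern], match_mode: str
) -> set[str]:
    """All k-mers selected by the binding model (exhaustive enumeration)."""
    for p in patterns:
        if match_mode == "exact" and p.width != k:
            raise ValueError(f"pattern {p} width {p.width} != k={k} in exact mode")
        if match_mode == "substring" and p.width > k:
            raise ValueError(f"pattern {p} wider than k={k}")
    matcher = iupac_match if match_mode == "exact" else iupac_search
    return {
        km for km in enumerate_inserts(k) if any(matcher(p, km) for p in patterns)
    }


def apply_selection(
    colonies: Sequence[str],
    binding_patterns: Sequence[IupacPattern | str],
    match_mode: str = "substring",
    fp_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Select colonies under the planted binding model.

    Returns the surviving insert multiset and a colony-level truth table
    (colony_id, insert, matched, survived).
    """
    patterns = [
        p if isinstance(p, IupacPattern) else IupacPattern(p) for p in binding_patterns
    ]
    k = len(colonies[0]) if colonies else 0
    match_set = _matching_insert_set(k, patterns, match_mode) if colonies else set()
    rng = np.random.default_rng(seed)
    matched = np.array([c in match_set for c in colonies], dtype=bool)
    lucky = rng.random(len(colonies)) < fp_rate
    survived = matched | lucky
    truth = pd.DataFrame(
        {
            "colony_id": np.arange(len(colonies)),
            "insert": list(colonies),
            "matched": matched,
            "survived": survived,
        }
    )
    survivors = [c for c, s in zip(colonies, survived) if s]
    return survivors, truth


def _quality_char_score(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, int(round(-10.0 * math.log10(error_rate))))


def emit_reads(
    survivors: Sequence[str],
    template: AmpliconTemplate,
    depth: int = 50,
    error_rate: float = 0.001,
    read_len: int = 150,
    paired: bool = False,
    seed: int = 0,
    colony_ids: Sequence[int] | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Emit amplicon reads for each surviving colony.

    Each read is the colony's rendered amplicon on a uniformly random strand,
    truncated to ``read_len``, with i.i.d. substitution errors; qualities are
    a constant Phred score matching ``error_rate``.  Paired mode emits mate 1
    from the chosen strand and mate 2 as the reverse complement (the mates
    overlap fully since the amplicon is shorter than the read length).

    Returns the reads and a read-level truth table mapping every read to its
    source colony.
    """
    amp_len = template.full_length
    if read_len < amp_len:
        raise ValueError(
            f"read_len {read_len} is shorter than the amplicon ({amp_len} nt); "
            "anchors would be truncated — use read_len >= template.full_length"
        )
    if colony_ids is None:
        colony_ids = list(range(len(survivors)))
    rng = np.random.default_rng(seed)
    q = _quality_char_score(error_rate)

    n = len(survivors) * depth
    reads: list[ReadRecord] = []
    truth_rows: dict[str, list] = {"read_id": [], "colony_id": [], "insert": []}
    if n == 0:
        return reads, pd.DataFrame(truth_rows)

    # Vectorize over all reads at once: amplicons share a fixed length.
    amps = np.empty((len(survivors), amp_len), dtype=np.int8)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    for i, insert in enumerate(survivors):
        amps[i] = lut[np.frombuffer(template.with_insert(insert).encode(), dtype=np.uint8)]

    mat = np.repeat(amps, depth, axis=0)  # (n, amp_len)
    flip = rng.random(n) < 0.5
    mat[flip] = _COMP[mat[flip]][:, ::-1]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
        mat = np.where(err, (mat + shift) % 4, mat)
    seqs = _BASES[mat]
    qual = [q] * amp_len
    for j in range(n):
        cid = colony_ids[j // depth]
        insert = survivors[j // depth]
        rid = f"sim_c{cid}_r{j % depth}"
        bases = seqs[j].tobytes().decode()
        if paired:
            reads.append(ReadRecord(rid + "/1", bases, list(qual)))
            mate2 = bases.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            reads.append(ReadRecord(rid + "/2", mate2, list(qual)))
        else:
            reads.append(ReadRecord(rid, bases, list(qual)))
        truth_rows["read_id"].append(rid)
        truth_rows["colony_id"].append(cid)
        truth_rows["insert"].append(insert)
    return reads, pd.DataFrame(truth_rows)


@dataclass
class SimulationResult:
    config: SimulationConfig
    reads: list[ReadRecord]
    colony_truth: pd.DataFrame
    read_truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        from .seqio import write_fastq

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, out / "reads.fastq")
        self.colony_truth.to_csv(out / "truth_colonies.tsv", sep="\t", index=False)
        self.read_truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        (out / "config.json").write_text(self.config.as_json() + "\n")


def run_simulation(
    config: SimulationConfig, template: AmpliconTemplate | None = None
) -> SimulationResult:
    """Run library sampling, selection and read emission end to end.

    The three stages draw from sub-seeds derived deterministically from
    ``config.seed`` so each stage is individually reproducible.
    """
    if template is None:
        template = design_template(config.k)
    if template.n_region_len != config.k:
        raise ValueError("template n_region_len must equal config.k")
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    colonies = sample_prey_library(config.n_colonies, config.k, seeds[0])
    survivors, colony_truth = apply_selection(
        colonies,
        config.binding_patterns,
        config.match_mode,
        config.fp_rate,
        seeds[1],
    )
    colony_ids = colony_truth.loc[colony_truth["survived"], "colony_id"].tolist()
    reads, read_truth = emit_reads(
        survivors,
        template,
        depth=config.depth,
        error_rate=config.error_rate,
        read_len=config.read_len,
        paired=config.paired,
        seed=seeds[2],
        colony_ids=colony_ids,
    )
    return SimulationResult(config, reads, colony_truth, read_truth)
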