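"""PWM motif discovery over the extracted inserts.

The pipeline has three stages:

1. **Seeding** — k-mers passing the enrichment thresholds are clustered
   greedily by Hamming distance: the highest-count unassigned k-mer seeds a
   cluster that absorbs every unassigned k-mer within ``radius`` of it.
2. **Refinement** — each cluster, at each candidate motif width w, is
   refined with an expectation-maximization under the OOPS model ("one
   occurrence per sequence"): every insert is assumed to contain exactly one
   motif occurrence at an unknown offset, with the remaining positions drawn
   from a uniform 0.25-per-base background.  The E-step computes posterior
   offset distributions under the current position frequency matrix; the
   M-step re-estimates the matrix with a pseudocount of 0.25 per cell.  The
   observed-data log-likelihood is non-decreasing at every iteration.
3. **Ranking** — refined models are scored by the log-likelihood ratio
   against the pure-background model and reported best-first.

Motifs are confined to the insert: the amplicon flanks are constant and
would dominate any motif allowed to cross the boundary.  By default the EM
runs on the *unique* insert set; a count-weighted mode is available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .extract import KmerTable
from .library_model import IUPAC_CODES

__all__ = [
    "MotifModel",
    "seed_clusters",
    "em_refine",
    "discover_motifs",
    "write_meme_minimal",
    "read_meme_minimal",
]

_ALPHABET = "ACGT"
_SET_TO_IUPAC = {codes: sym for sym, codes in IUPAC_CODES.items()}


def _encode(sequences: Sequence[str]) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
    arr = np.stack(
        [lut[np.frombuffer(s.upper().encode(), dtype=np.uint8)] for s in sequences]
    )
    if (arr < 0).any():
        raise ValueError("sequences must be pure A/C/G/T")
    return arr


@dataclass
class MotifModel:
    """A position frequency matrix of width w with its supporting evidence.

    ``pfm`` has shape (w, 4), column order A, C, G, T; every row sums to 1
    and, being pseudocounted, has no zero entries.
    """

    pfm: np.ndarray
    nsites: int
    log_likelihood: float
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=np.float64)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError("pfm must have shape (w, 4)")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pfm rows must sum to 1")
        if (self.pfm <= 0).any():
            raise ValueError("pfm must be strictly positive (pseudocounted)")

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        """Most-probable base at each position."""
        return "".join(_ALPHABET[i] for i in self.pfm.argmax(axis=1))

    @property
    def iupac_consensus(self) -> str:
        """Degenerate rendering: bases holding >= 30% of a column's mass."""
        out = []
        for row in self.pfm:
            bases = frozenset(b for b, p in zip(_ALPHABET, row) if p >= 0.30)
            if not bases:
                bases = frozenset(_ALPHABET[int(row.argmax())])
            out.append(_SET_TO_IUPAC[bases])
        return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def seed_clusters(
    enriched: pd.DataFrame,
    q_max: float = 0.05,
    min_fold: float = 2.0,
    radius: int = 1,
) -> list[list[str]]:
    """Greedy Hamming clustering of the enriched k-mers.

    K-mers with ``q_value <= q_max`` and ``fold >= min_fold`` are considered;
    repeatedly, the highest-count unassigned k-mer (ties broken
    lexicographically) seeds a cluster absorbing every unassigned k-mer
    within ``radius`` of the seed.  The seed is the first member of each
    cluster.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    passing = enriched[
        (enriched["q_value"] <= q_max) & (enriched["fold"] >= min_fold)
    ]
    ordered = passing.sort_values(
        ["count", "kmer"], ascending=[False, True], kind="mergesort"
    )["kmer"].tolist()
    clusters: list[list[str]] = []
    unassigned = list(ordered)
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed] + [km for km in unassigned if _hamming(seed, km) <= radius]
        unassigned = [km for km in unassigned if km not in members]
        clusters.append(members)
    return clusters


def _consensus_init(consensus: str, major: float = 0.7) -> np.ndarray:
    """PFM with ``major`` mass on the consensus base, the rest spread evenly."""
    minor = (1.0 - major) / 3.0
    pfm = np.full((len(consensus), 4), minor)
    for j, base in enumerate(consensus):
        pfm[j, _ALPHABET.index(base)] = major
    return pfm


def em_refine(
    sequences: Sequence[str],
    w: int,
    init: MotifModel | np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    weights: Sequence[float] | None = None,
    pseudocount: float = 0.25,
) -> MotifModel:
    """Refine a motif of width ``w`` on equal-length inserts by OOPS EM.

    Each sequence is assumed to contain exactly one motif occurrence at a
    uniform-prior offset in [0, k-w]; off-motif positions follow the uniform
    background.  Iterates until the log-likelihood gain drops below ``tol``
    or ``max_iter`` is reached; the trace of log-likelihoods (one per
    iteration, non-decreasing) is kept on the returned model.
    """
    if not sequences:
        raise ValueError("no sequences to refine on")
    X = _encode(sequences)
    n, k = X.shape
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("sequences must have equal length")
    if not 1 <= w <= k:
        raise ValueError(f"width {w} out of range [1, {k}]")
    pfm = init.pfm if isinstance(init, MotifModel) else np.asarray(init, dtype=np.float64)
    if pfm.shape != (w, 4):
        raise ValueError(f"init pfm shape {pfm.shape} != ({w}, 4)")
    if (pfm <= 0).any() or not np.allclose(pfm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("init pfm is degenerate (zero entries or rows not summing to 1)")
    pfm = pfm / pfm.sum(axis=1, keepdims=True)
    wts = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    if wts.shape != (n,) or (wts <= 0).any():
        raise ValueError("weights must be positive, one per sequence")

    n_off = k - w + 1
    log_bg = np.log(0.25)
    # windows[i, o, j] = base at offset o+j of sequence i
    idx = np.arange(n_off)[:, None] + np.arange(w)[None, :]
    windows = X[:, idx]  # (n, n_off, w)

    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_pfm = np.log(pfm)
        # log P(window | motif) - log P(window | background), per offset
        scores = log_pfm[np.arange(w)[None, None, :], windows].sum(axis=2)
        scores = scores - w * log_bg  # (n, n_off)
        # observed-data LL: off-motif bases at background, uniform offset prior
        per_seq = logsumexp(scores, axis=1) - np.log(n_off) + k * log_bg
        ll = float((wts * per_seq).sum())
        ll_trace.append(ll)
        # E-step: posterior offset responsibilities
        z = np.exp(scores - logsumexp(scores, axis=1, keepdims=True))  # (n, n_off)
        # M-step: expected base counts per motif column, pseudocounted
        counts = np.full((w, 4), pseudocount)
        wz = z * wts[:, None]
        for b in range(4):
            counts[:, b] += np.einsum("no,noj->j", wz, (windows == b).astype(np.float64))
        pfm = counts / counts.sum(axis=1, keepdims=True)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return MotifModel(
        pfm=pfm, nsites=n, log_likelihood=ll_trace[-1], ll_trace=ll_trace
    )


def _best_seed_wmer(members: Sequence[str], counts: dict[str, int], w: int) -> str:
    """Most frequent w-substring of the cluster members, count-weighted."""
    tally: Counter[str] = Counter()
    for km in members:
        weight = counts.get(km, 1)
        for i in range(len(km) - w + 1):
            tally[km[i : i + w]] += weight
    best = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0]


def discover_motifs(
    table: KmerTable,
    widths: Sequence[int] | None = None,
    q_max: float = 0.05,
    min_fold: float = 2.0,
    radius: int = 1,
    weighted: bool = False,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[MotifModel]:
    """Full discovery pipeline: enrichment -> seeding -> EM -> ranking.

    For each cluster and each candidate width, EM is initialized from the
    cluster's most frequent w-substring (0.7 mass on each consensus base) and
    run on the cluster's unique members; the best width per cluster is kept
    and clusters are ranked by log-likelihood ratio against the background
    model.  Returns an empty list when no k-mer passes the thresholds.
    """
    from .enrich import kmer_enrichment

    k = table.k
    if widths is None:
        widths = range(min(4, k), k + 1)
    widths = sorted(set(widths))
    if any(w < 1 or w > k for w in widths):
        raise ValueError(f"widths must lie within [1, {k}]")

    enriched = kmer_enrichment(table)
    clusters = seed_clusters(enriched, q_max=q_max, min_fold=min_fold, radius=radius)
    models: list[MotifModel] = []
    for members in clusters:
        sequences = sorted(members)
        wts = [table.counts.get(s, 1) for s in sequences] if weighted else None
        bg_ll = (sum(wts) if wts else len(sequences)) * k * np.log(0.25)
        best: tuple[float, int, MotifModel] | None = None
        for w in widths:
            seed = _best_seed_wmer(sequences, table.counts, w)
            model = em_refine(
                sequences,
                w,
                _consensus_init(seed),
                max_iter=max_iter,
                tol=tol,
                weights=wts,
            )
            llr = model.log_likelihood - bg_ll
            if best is None or (llr, -w) > (best[0], -best[1]):
                best = (llr, w, model)
        if best is not None:
            best[2].score = best[0]  # type: ignore[attr-defined]
            models.append(best[2])
    models.sort(key=lambda m: (-getattr(m, "score", 0.0), m.consensus))
    return models


def motif_summary(models: Sequence[MotifModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "consensus": [m.consensus for m in models],
            "iupac": [m.iupac_consensus for m in models],
            "width": [m.width for m in models],
            "nsites": [m.nsites for m in models],
            "score": [getattr(m, "score", np.nan) for m in models],
        }
    )


def write_meme_minimal(
    motifs: Sequence[MotifModel],
    path: str | Path | IO[str],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write motifs in MEME minimal motif format (interoperable with the
    MEME suite's downstream tools)."""

    def _write(handle: IO[str]) -> None:
        handle.write("MEME version 4\n\n")
        handle.write("ALPHABET= ACGT\n\n")
        handle.write("strands: + -\n\n")
        handle.write("Background letter frequencies\n")
        handle.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(_ALPHABET, background)) + "\n\n"
        )
        for i, m in enumerate(motifs, start=1):
            handle.write(f"MOTIF m{i} {m.consensus}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.nsites} E= 0\n"
            )
            for row in m.pfm:
                handle.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            handle.write("\n")

    if hasattr(path, "write"):
        _write(path)  # type: ignore[arg-type]
    else:
        with open(path, "w") as handle:
            _write(handle)


def read_meme_minimal(path: str | Path) -> list[MotifModel]:
    """Parse a MEME minimal motif file back into models (lossless to the
    written 6-decimal precision; rows are renormalized to sum exactly to 1)."""
    models: list[MotifModel] = []
    with open(path) as handle:
        lines = iter(handle.read().splitlines())
    for line in lines:
        if not line.startswith("MOTIF"):
            continue
        header = next(lines)
        parts = header.split()
        fields = dict(zip(parts[2::2], parts[3::2]))  # alength=, w=, nsites=, E=
        w = int(fields["w="])
        nsites = int(fields["nsites="])
        rows = [list(map(float, next(lines).split())) for _ in range(w)]
        pfm = np.asarray(rows)
        pfm = pfm / pfm.sum(axis=1, keepdims=True)
        models.append(MotifModel(pfm=pfm, nsites=nsites, log_likelihood=np.nan))
    return models
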