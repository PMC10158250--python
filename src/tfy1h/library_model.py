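"""Amplicon design of the random-insert prey library and basic sequence algebra.

The prey library inserts a short fully random N-region into the SmaI site of
the pHIS2 reporter vector between two fixed homology flanks.  The amplicon
sequenced after selection therefore has the structure

    upstream_flank + N*k + downstream_flank

with the upstream flank ending in ``CCC`` and the downstream flank beginning
with ``GGG`` (the reconstituted SmaI half-sites).  Everything downstream of
the wet lab — insert extraction, enrichment, motif discovery — is defined
relative to this template, so it lives here together with the small pieces of
sequence algebra the rest of the package shares: IUPAC degenerate matching,
reverse complementation and exhaustive k-mer enumeration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from itertools import product
from pathlib import Path

__all__ = [
    "AmpliconTemplate",
    "IupacPattern",
    "GCC_BOX",
    "DRE_CRT",
    "SSINS_TEXT",
    "build_template",
    "parse_template",
    "default_template",
    "design_template",
    "template_from_config",
    "template_to_config",
    "write_template_fasta",
    "enumerate_inserts",
    "iupac_match",
    "reverse_complement",
]

#: The 125-nt single-strand insertion oligo (SsInS) used to build the prey
#: library, as printed: fixed pHIS2-homologous flanks around a random N-region.
SSINS_TEXT = (
    "TGTAAAACGACGGCCAGTGAATTGTAATACGACTCACTATAGGGCGAATTCCC"
    "NNNNNNNNN"
    "GGGGAGCTCACGCGTTCGCGAATCGATCCGCGGTCTAGAAATTCCTGGCATTATCACATAATG"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Base sets of the 15 IUPAC nucleotide codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def _validate_acgt(seq: str, what: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(
                f"{what} contains non-ACGT character {base!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class AmpliconTemplate:
    """The fixed amplicon design: two constant flanks around a k-nt N-region.

    Coordinates are 0-based half-open throughout the package.
    """

    upstream_flank: str
    n_region_len: int
    downstream_flank: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "upstream_flank", _validate_acgt(self.upstream_flank, "upstream flank")
        )
        object.__setattr__(
            self,
            "downstream_flank",
            _validate_acgt(self.downstream_flank, "downstream flank"),
        )
        if not self.upstream_flank or not self.downstream_flank:
            raise ValueError("flanks must be non-empty")
        if self.n_region_len < 0:
            raise ValueError("n_region_len must be >= 0")

    @property
    def full_length(self) -> int:
        return len(self.upstream_flank) + self.n_region_len + len(self.downstream_flank)

    @property
    def insert_interval(self) -> tuple[int, int]:
        """0-based half-open coordinates of the N-region in the rendered text."""
        start = len(self.upstream_flank)
        return start, start + self.n_region_len

    def render(self) -> str:
        return self.upstream_flank + "N" * self.n_region_len + self.downstream_flank

    def with_insert(self, insert: str) -> str:
        """Rendered amplicon with the N-region replaced by a concrete insert."""
        insert = _validate_acgt(insert, "insert")
        if len(insert) != self.n_region_len:
            raise ValueError(
                f"insert length {len(insert)} != n_region_len {self.n_region_len}"
            )
        return self.upstream_flank + insert + self.downstream_flank


def build_template(
    upstream_flank: str, n_region_len: int, downstream_flank: str
) -> AmpliconTemplate:
    """Build a template from its parts, validating the flank alphabet."""
    return AmpliconTemplate(upstream_flank, n_region_len, downstream_flank)


def parse_template(text: str) -> AmpliconTemplate:
    """Parse a rendered template (flanks + run of N) such as the SsInS oligo.

    The N-region is located as the unique run of ``N`` in the text; the parse
    is rejected if there is no run or more than one (flanks must be pure
    A/C/G/T).
    """
    text = text.upper()
    runs = [(m.start(), m.end()) for m in re.finditer("N+", text)]
    if not runs:
        raise ValueError("template text contains no N-region")
    if len(runs) > 1:
        raise ValueError(f"template text contains {len(runs)} N-runs; expected one")
    start, end = runs[0]
    if start == 0 or end == len(text):
        raise ValueError("N-region must be flanked on both sides")
    return AmpliconTemplate(text[:start], end - start, text[end:])


def default_template() -> AmpliconTemplate:
    """The packaged SsInS design exactly as printed (125 nt, 9-nt N-region).

    Note the printed oligo carries nine N's although the screen was designed
    around 7-nt inserts; use :func:`design_template` for the 7-nt variant with
    the same flanks.
    """
    return parse_template(SSINS_TEXT)


def design_template(k: int = 7) -> AmpliconTemplate:
    """The SsInS flanks around a k-nt N-region (default the 7-nt design)."""
    base = default_template()
    return AmpliconTemplate(base.upstream_flank, k, base.downstream_flank)


def template_from_config(path: str | Path) -> AmpliconTemplate:
    """Load a template from a JSON config with fields
    upstream_flank / n_region_len / downstream_flank."""
    with open(path) as handle:
        cfg = json.load(handle)
    return AmpliconTemplate(
        cfg["upstream_flank"], int(cfg["n_region_len"]), cfg["downstream_flank"]
    )


def template_to_config(template: AmpliconTemplate, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(
            {
                "upstream_flank": template.upstream_flank,
                "n_region_len": template.n_region_len,
                "downstream_flank": template.downstream_flank,
            },
            handle,
            indent=2,
        )
        handle.write("\n")


def write_template_fasta(template: AmpliconTemplate, path: str | Path, name: str = "amplicon_template") -> None:
    with open(path, "w") as handle:
        handle.write(f">{name} length={template.full_length}\n{template.render()}\n")


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate nucleotide pattern over the 15 IUPAC codes."""

    symbols: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", self.symbols.upper())
        for i, code in enumerate(self.symbols):
            if code not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {code!r} at position {i}")

    @property
    def width(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols


#: The GCC-Box element bound by ERF-family transcription factors.
GCC_BOX = IupacPattern("AGCCGCC")
#: The dehydration-responsive element DRE/CRT ((A/G)GCCGA), A/G encoded R.
DRE_CRT = IupacPattern("RGCCGA")


def enumerate_inserts(k: int) -> list[str]:
    """All 4**k k-mers over {A,C,G,T} in lexicographic order.

    Bounded at k <= 12 to guard against combinatorial blowup.
    """
    if not 0 <= k <= 12:
        raise ValueError(f"k must be in [0, 12], got {k}")
    return ["".join(p) for p in product("ACGT", repeat=k)]


def iupac_match(pattern: IupacPattern | str, window: str) -> bool:
    """True iff every base of ``window`` lies in the base set of the
    corresponding IUPAC code of ``pattern``; widths must agree."""
    if isinstance(pattern, str):
        pattern = IupacPattern(pattern)
    window = window.upper()
    if len(window) != pattern.width:
        raise ValueError(
            f"window length {len(window)} != pattern width {pattern.width}"
        )
    return all(base in IUPAC_CODES[code] for code, base in zip(pattern.symbols, window))


def iupac_search(pattern: IupacPattern | str, seq: str) -> bool:
    """True iff ``seq`` contains a match of ``pattern`` at any offset."""
    if isinstance(pattern, str):
        pattern = IupacPattern(pattern)
    seq = seq.upper()
    w = pattern.width
    return any(iupac_match(pattern, seq[i : i + w]) for i in range(len(seq) - w + 1))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N; involution."""
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in "ACGTN":
            raise ValueError(f"invalid character {base!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]
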