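"""Reading samtools pileup text.

The 6-column pileup line is::

    chrom  pos  ref  depth  read-bases  qualities

with 1-based positions.  The read-bases string uses the samtools
conventions: "." and "," are reference matches on the forward and reverse
strand, upper/lower-case letters are mismatches by strand, "^X" marks a
read start (X encodes the mapping quality and is consumed without emitting
an observation), "$" marks a read end, "+n<seq>"/"-n<seq>" are indels
attached to the preceding observation, and "*" is a deletion placeholder
that consumes a quality character.

Decoded observations are reduced to the two-symbol representation used by
the caller: reads matching the reference count toward ``n_R``, any other
A/C/G/T base counts toward ``n_A`` regardless of identity; deletion
placeholders and "N" calls are excluded from the used depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, TextIO

from .errors import phred_to_error

__all__ = [
    "Observation",
    "PileupSite",
    "SiteCounts",
    "PileupParseError",
    "parse_pileup_line",
    "iter_pileup",
    "reduce_to_counts",
]

REF_MATCH = "="   # marker for "." / "," observations
DELETION = "*"

_BASES = frozenset("ACGTN")


class PileupParseError(ValueError):
    """Raised for malformed pileup input; carries the line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        where = f" (line {line_number})" if line_number is not None else ""
        super().__init__(f"{message}{where}")
        self.line_number = line_number


class Observation(NamedTuple):
    """One read base at a site: base symbol, strand and quality character.

    ``base`` is one of A/C/G/T/N, the ref-match marker "=" or the deletion
    marker "*".
    """

    base: str
    strand: str
    quality_char: str


@dataclass
class PileupSite:
    """One decoded pileup line."""

    chrom: str
    pos: int
    ref: str
    depth_reported: int
    observations: list[Observation] = field(default_factory=list)

    @property
    def skip(self) -> bool:
        """True when no R/A split is definable (reference base N)."""
        return self.ref == "N"


@dataclass
class SiteCounts:
    """Two-class reduction of a site: used depth C, alternative count n_A,
    and the per-class error probabilities derived from the qualities."""

    chrom: str
    pos: int
    ref: str
    alt: Optional[str]
    C: int
    n_A: int
    quals_R: list[float]
    quals_A: list[float]
    skip: bool = False

    @property
    def n_R(self) -> int:
        return self.C - self.n_A


def parse_pileup_line(line: str, line_number: Optional[int] = None) -> PileupSite:
    """Decode one 6-column pileup line into per-read observations."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(
            f"expected >=6 tab-separated fields, got {len(fields)}", line_number
        )
    chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(f"non-integer position {pos_s!r}", line_number)
    if pos < 1:
        raise PileupParseError(f"position {pos} < 1", line_number)
    try:
        depth = int(depth_s)
    except ValueError:
        raise PileupParseError(f"non-integer depth {depth_s!r}", line_number)
    ref = ref.upper()
    if ref not in _BASES:
        raise PileupParseError(f"reference base {ref!r} not in A/C/G/T/N", line_number)

    site = PileupSite(chrom=chrom, pos=pos, ref=ref, depth_reported=depth)
    if depth == 0:
        # samtools writes "*\t*" placeholders for empty sites
        return site

    observations: list[tuple[str, str]] = []  # (base, strand), quality paired later
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' read-start marker", line_number)
            i += 2  # skip the mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"indel marker {c!r} without length", line_number
                )
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise PileupParseError(
                    f"indel length {length} overruns base string", line_number
                )
            i = j + length
        elif c in ".,":
            observations.append((REF_MATCH, "+" if c == "." else "-"))
            i += 1
        elif c == DELETION:
            observations.append((DELETION, "+"))
            i += 1
        elif c.upper() in _BASES:
            observations.append((c.upper(), "+" if c.isupper() else "-"))
            i += 1
        elif c in "<>":
            # reference-skip placeholders (CIGAR N); excluded like deletions
            observations.append((DELETION, "+" if c == ">" else "-"))
            i += 1
        else:
            raise PileupParseError(
                f"unrecognized character {c!r} in read-bases string", line_number
            )

    if len(observations) != len(quals):
        raise PileupParseError(
            f"{len(observations)} base observations but {len(quals)} quality "
            "characters",
            line_number,
        )
    site.observations = [
        Observation(base, strand, q)
        for (base, strand), q in zip(observations, quals)
    ]
    return site


def iter_pileup(handle: TextIO | Iterable[str]) -> Iterator[PileupSite]:
    """Iterate decoded sites from a pileup stream, skipping blank lines."""
    for ln, line in enumerate(handle, start=1):
        if not line.strip():
            continue
        yield parse_pileup_line(line, line_number=ln)


def reduce_to_counts(site: PileupSite, offset: int = 33) -> SiteCounts:
    """Reduce a decoded site to the two-class (R/A) representation.

    Deletion placeholders and N base calls are excluded from the used
    depth.  The ``alt`` label is the most frequent non-reference base
    (ties broken lexicographically); it is reporting metadata only — all
    non-reference bases count toward ``n_A``.
    """
    if site.skip:
        return SiteCounts(site.chrom, site.pos, site.ref, None, 0, 0, [], [],
                          skip=True)
    quals_R: list[float] = []
    quals_A: list[float] = []
    alt_counts: dict[str, int] = {}
    for obs in site.observations:
        if obs.base in (DELETION, "N"):
            continue
        err = phred_to_error(obs.quality_char, offset=offset)
        if obs.base == REF_MATCH or obs.base == site.ref:
            quals_R.append(err)
        else:
            quals_A.append(err)
            alt_counts[obs.base] = alt_counts.get(obs.base, 0) + 1
    alt = None
    if alt_counts:
        alt = min(alt_counts, key=lambda b: (-alt_counts[b], b))
    n_A = len(quals_A)
    return SiteCounts(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=alt,
        C=n_A + len(quals_R),
        n_A=n_A,
        quals_R=quals_R,
        quals_A=quals_A,
    )
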