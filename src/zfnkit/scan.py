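"""Genome-wide off-target scanning for a ZFN half-site pair.

A cleavable site is any FokI-compatible arrangement of the two 9-bp
half-sites (and/or their reverse complements, covering homodimeric
binding) separated by a spacer of variable length whose bases are not
read by the zinc fingers.  The scanner enumerates every composite
pattern — one 9-mer, an N-run spacer, another 9-mer — over the
configured arrangements and spacer lengths, slides each pattern over
both strands of a genome counting mismatches only at the 18 half-site
positions, and reports hits with flanking context for downstream
verification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .design import HalfSite
from .seqio import SequenceRecord, reverse_complement, write_bed6, write_fasta

__all__ = [
    "ScanConfig",
    "ScanPattern",
    "ScanHit",
    "DEFAULT_ARRANGEMENTS",
    "enumerate_patterns",
    "scan_genome",
    "variation_percent",
    "extract_context",
    "write_hits",
]

HALF_SITE_POSITIONS = 18

# An arrangement "A-B" names a composite A + N^spacer + B — the two
# literal patterns handed to a grep-style scan with the spacer as free
# positions between them.  Elements may be L, R, Lrc or Rrc (the
# reverse-complemented 9-mers); an "rc:" prefix takes the reverse
# complement of the whole composite.  The default set enumerates every
# dimer geometry of the pair: the four tail-to-tail composites
# revcomp(A) + spacer + B (e.g. "Lrc-R" is the canonical heterodimer,
# whose top strand reads revcomp(left) + spacer + right) and the four
# head-to-head composites A + spacer + revcomp(B).  Each subset is closed
# under reverse complement, so a single-strand text scan still detects
# bottom-strand sites; for distinct non-palindromic half-sites all 8 are
# distinct, hence 8 x 7 = 56 patterns over the default spacer range 4-10.
DEFAULT_ARRANGEMENTS: tuple[str, ...] = (
    "Lrc-L", "Lrc-R", "Rrc-L", "Rrc-R",
    "L-Lrc", "L-Rrc", "R-Lrc", "R-Rrc",
)


@dataclass(frozen=True)
class ScanConfig:
    """Configuration of the pattern enumeration and scan."""

    spacer_min: int = 4
    spacer_max: int = 10
    arrangements: tuple[str, ...] = DEFAULT_ARRANGEMENTS
    max_mismatches: int = 0
    flank_up: int = 100
    flank_down: int = 100

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max or self.spacer_min < 0:
            raise ValueError("invalid spacer range")
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flank lengths must be >= 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def spacer_range(self) -> range:
        return range(self.spacer_min, self.spacer_max + 1)


@dataclass(frozen=True)
class ScanPattern:
    """A composite pattern: 9-mer + N-run spacer + 9-mer."""

    pattern_id: str
    composite: str
    arrangement_label: str
    spacer_length: int

    def __post_init__(self) -> None:
        n_run = "N" * self.spacer_length
        if (
            len(self.composite) != 18 + self.spacer_length
            or self.composite[9 : 9 + self.spacer_length] != n_run
            or "N" in self.composite[:9]
            or "N" in self.composite[9 + self.spacer_length :]
        ):
            raise ValueError(f"malformed composite {self.composite!r}")


@dataclass(frozen=True)
class ScanHit:
    """A genomic match of a composite pattern."""

    contig: str
    start: int  # 0-based half-open, top-strand coordinates
    end: int
    strand: str  # '+' or '-'
    pattern_id: str
    mismatches: int

    @property
    def variation(self) -> float:
        return variation_percent(self.mismatches)


def variation_percent(mismatches: int) -> float:
    """Percent divergence from the intended site over the 18 read positions."""
    if not 0 <= mismatches <= HALF_SITE_POSITIONS:
        raise ValueError(f"mismatch count {mismatches} outside 0..{HALF_SITE_POSITIONS}")
    return 100.0 * mismatches / HALF_SITE_POSITIONS


def _element(key: str, L: str, R: str) -> str:
    try:
        return {"L": L, "R": R, "Lrc": reverse_complement(L), "Rrc": reverse_complement(R)}[key]
    except KeyError as exc:
        raise ValueError(f"unknown arrangement element {key!r}") from exc


def enumerate_patterns(
    left: HalfSite | str,
    right: HalfSite | str,
    config: ScanConfig | None = None,
) -> list[ScanPattern]:
    """Enumerate distinct composite patterns for a half-site pair.

    For each enabled arrangement and each spacer length in the configured
    range, one composite is built; exact duplicates (possible for
    palindromic or identical half-sites) are removed keeping the first in
    the deterministic (arrangement, spacer) order.  With the published
    NF-YA8 half-sites and defaults this yields 8 x 7 = 56 patterns.
    """
    config = config or ScanConfig()
    L = left.sequence if isinstance(left, HalfSite) else HalfSite(left).sequence
    R = right.sequence if isinstance(right, HalfSite) else HalfSite(right).sequence
    patterns: list[ScanPattern] = []
    seen: set[str] = set()
    for label in config.arrangements:
        rc = label.startswith("rc:")
        pair = label[3:] if rc else label
        parts = pair.split("-")
        if len(parts) != 2:
            raise ValueError(f"unknown arrangement label {label!r}")
        a, b = (_element(k, L, R) for k in parts)
        for spacer in config.spacer_range:
            comp = a + "N" * spacer + b
            if rc:
                comp = reverse_complement(comp)
            if comp in seen:
                continue
            seen.add(comp)
            patterns.append(
                ScanPattern(
                    pattern_id=f"{label}_s{spacer}",
                    composite=comp,
                    arrangement_label=label,
                    spacer_length=spacer,
                )
            )
    return patterns


def _mismatch_counts(contig: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatches of ``pattern`` at every offset of ``contig`` (uint8 array).

    Pattern N positions are fully degenerate; genome N never matches a
    concrete pattern base (it differs bytewise, so it counts a mismatch).
    """
    m = len(pattern)
    n_win = len(contig) - m + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n_win, dtype=np.int32)
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    for j in range(m):
        if pattern[j] == "N":
            continue
        counts += contig[j : j + n_win] != pat[j]
    return counts


def scan_genome(
    genome: Sequence[SequenceRecord],
    patterns: Sequence[ScanPattern],
    max_mismatches: int = 0,
) -> list[ScanHit]:
    """Scan both strands of every contig for every pattern.

    All matches with at most ``max_mismatches`` mismatches over the 18
    half-site positions are reported in top-strand coordinates, including
    overlapping and self-overlapping matches.  Hits are sorted by
    (contig, start, strand, pattern_id).
    """
    if not genome:
        raise ValueError("genome must contain at least one contig")
    hits: list[ScanHit] = []
    for rec in genome:
        contig = np.frombuffer(rec.sequence.upper().encode("ascii"), dtype=np.uint8)
        for pat in patterns:
            for strand, probe in (("+", pat.composite), ("-", reverse_complement(pat.composite))):
                counts = _mismatch_counts(contig, probe)
                for off in np.flatnonzero(counts <= max_mismatches):
                    off = int(off)
                    hits.append(
                        ScanHit(
                            contig=rec.identifier,
                            start=off,
                            end=off + len(probe),
                            strand=strand,
                            pattern_id=pat.pattern_id,
                            mismatches=int(counts[off]),
                        )
                    )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand, h.pattern_id))
    return hits


def extract_context(
    genome: SequenceRecord,
    hit: ScanHit,
    flank_up: int = 100,
    flank_down: int = 100,
) -> tuple[str, str, str, bool]:
    """Extract (upstream, match, downstream, truncated) around a hit.

    Flanks are oriented to the hit's strand: for a minus-strand hit the
    sequences are reverse-complemented and "upstream" is 5' of the match
    as read on the minus strand.  ``truncated`` is set when either flank
    is clipped at a contig edge.  Defaults give 100 + 100 = 200 nt of
    combined flanking context.
    """
    seq = genome.sequence
    if not (0 <= hit.start <= hit.end <= len(seq)):
        raise ValueError(
            f"hit {hit.start}-{hit.end} outside contig {genome.identifier} "
            f"of length {len(seq)}"
        )
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flank lengths must be >= 0")
    if hit.strand == "+":
        up_lo = max(0, hit.start - flank_up)
        down_hi = min(len(seq), hit.end + flank_down)
        upstream = seq[up_lo : hit.start]
        match = seq[hit.start : hit.end]
        downstream = seq[hit.end : down_hi]
        truncated = len(upstream) < flank_up or len(downstream) < flank_down
    else:
        # 5' of the minus-strand match lies at higher top-strand coordinates.
        up_hi = min(len(seq), hit.end + flank_up)
        down_lo = max(0, hit.start - flank_down)
        upstream = reverse_complement(seq[hit.end : up_hi])
        match = reverse_complement(seq[hit.start : hit.end])
        downstream = reverse_complement(seq[down_lo : hit.start])
        truncated = len(upstream) < flank_up or len(downstream) < flank_down
    return upstream, match, downstream, truncated


def write_hits(
    hits: Sequence[ScanHit],
    bed_path: str | os.PathLike,
    contexts: Sequence[tuple[str, str, str, bool]] | None = None,
    fasta_path: str | os.PathLike | None = None,
) -> None:
    """Write hits as BED6 and, optionally, their contexts as FASTA.

    BED records are 0-based half-open with score = mismatch count and
    name = pattern id.  FASTA headers encode contig:start-end:strand:pattern_id;
    each context record is upstream + match + downstream as one sequence.
    """
    write_bed6(
        [(h.contig, h.start, h.end, h.pattern_id, h.mismatches, h.strand) for h in hits],
        bed_path,
    )
    if contexts is not None:
        if fasta_path is None:
            raise ValueError("fasta_path required when contexts are given")
        if len(contexts) != len(hits):
            raise ValueError("contexts must parallel hits")
        records = [
            SequenceRecord(
                f"{h.contig}:{h.start}-{h.end}:{h.strand}:{h.pattern_id}",
                up + match + down,
            )
            for h, (up, match, down, _t) in zip(hits, contexts)
        ]
        write_fasta(records, fasta_path)
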