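"""Deterministic synthetic test-data generators with truth tables.

Two generators support end-to-end validation of the toolkit: random
genomes with composite target sites planted at known coordinates (with
controlled numbers of half-site mismatches), and mutant clone sets drawn
from a configured mutation spectrum over a reference CDS.  Both are
bit-reproducible given a seed and emit machine-readable truth tables so
downstream scanning/genotyping output can be checked without re-derivation.

The default spectrum (51.5% SNV / 39.4% indel / 9.1% complex, edits
concentrated in the nuclease target window and a downstream hotspot)
emulates the published NF-YA8 clone analysis; the generators draw
uniform-composition background sequence and single primary edits per
clone, so they do not model GC bias, sequencing error or multi-allelic
clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotyping import EditCall, _left_shift, apply_edits, classify_consequence
from .scan import ScanPattern
from .seqio import CdsWindow, SequenceRecord, reverse_complement

__all__ = [
    "PlantSpec",
    "SpectrumConfig",
    "make_synthetic_genome",
    "make_mutant_clones",
    "make_random_cds",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """A composite site to plant in a synthetic genome.

    ``mismatch_positions`` are indices into the 18 half-site positions
    (0-8 left 9-mer, 9-17 right 9-mer) to corrupt with a different base.
    """

    pattern: ScanPattern | str
    offset: int
    strand: str = "+"
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if any(not 0 <= i < 18 for i in self.mismatch_positions):
            raise ValueError("mismatch positions must be half-site indices 0..17")

    @property
    def composite(self) -> str:
        return (
            self.pattern.composite
            if isinstance(self.pattern, ScanPattern)
            else self.pattern.upper()
        )

    @property
    def pattern_id(self) -> str:
        return (
            self.pattern.pattern_id
            if isinstance(self.pattern, ScanPattern)
            else "planted"
        )


def make_synthetic_genome(
    length: int,
    plants: Sequence[PlantSpec],
    seed: int,
    contig_id: str = "chrS",
) -> tuple[SequenceRecord, pd.DataFrame]:
    """A random genome with composite sites planted at known offsets.

    Background bases are uniform over {A,C,G,T}.  Each plant's spacer N's
    are filled with random bases, the requested half-site positions are
    corrupted, and minus-strand plants are written reverse-complemented.
    Returns the contig and a truth table (contig, start, end, strand,
    pattern_id, mismatches).  Overlapping or out-of-bounds plants raise.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    intervals: list[tuple[int, int]] = []
    rows = []
    for plant in sorted(plants, key=lambda p: p.offset):
        comp = plant.composite
        start, end = plant.offset, plant.offset + len(comp)
        if start < 0 or end > length:
            raise ValueError(f"plant at {start} does not fit in genome of length {length}")
        for s, e in intervals:
            if start < e and s < end:
                raise ValueError(f"plant at {start} overlaps plant at {s}")
        intervals.append((start, end))

        # Half-site (non-N) indices of the composite, left 9-mer then right.
        half_idx = [i for i, b in enumerate(comp) if b != "N"]
        realized = [
            b if b != "N" else str(rng.choice(_BASES)) for b in comp
        ]
        for hs_pos in plant.mismatch_positions:
            i = half_idx[hs_pos]
            others = [b for b in "ACGT" if b != comp[i]]
            realized[i] = str(rng.choice(np.array(others)))
        site = "".join(realized)
        if plant.strand == "-":
            site = reverse_complement(site)
        seq[start:end] = list(site)
        rows.append(
            dict(
                contig=contig_id,
                start=start,
                end=end,
                strand=plant.strand,
                pattern_id=plant.pattern_id,
                mismatches=len(plant.mismatch_positions),
            )
        )
    truth = pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "pattern_id", "mismatches"]
    )
    return SequenceRecord(contig_id, "".join(seq)), truth


_STOPS = {"TAA", "TAG", "TGA"}


def make_random_cds(n_codons: int, seed: int) -> str:
    """A random CDS: ATG + (n_codons - 2) random sense codons + TAA stop."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one sense, stop)")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclass(frozen=True)
class SpectrumConfig:
    """Mutation-spectrum configuration for the clone generator.

    Defaults follow the published NF-YA8 clone analysis: 51.5% SNV,
    39.4% indel, 9.1% complex, with edits placed in the nuclease target
    window (CDS 689-713) or the downstream indel hotspot (873-935).
    Indel lengths (1, 2, 3, 6) with probabilities (0.4, 0.2, 0.3, 0.1)
    give P(frameshift | indel) = 0.6, near the published ratio of
    frameshift-inducing indels to all indels.
    """

    p_snv: float = 0.515
    p_indel: float = 0.394
    p_complex: float = 0.091
    indel_lengths: tuple[int, ...] = (1, 2, 3, 6)
    indel_length_probs: tuple[float, ...] = (0.4, 0.2, 0.3, 0.1)
    windows: tuple[CdsWindow, ...] = (CdsWindow(689, 713), CdsWindow(873, 935))
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_snv + self.p_indel + self.p_complex
        if not np.isclose(total, 1.0):
            raise ValueError(f"category proportions must sum to 1, got {total}")
        if any(p < 0 for p in (self.p_snv, self.p_indel, self.p_complex)):
            raise ValueError("proportions must be non-negative")
        if len(self.indel_lengths) != len(self.indel_length_probs):
            raise ValueError("indel length distribution is malformed")
        if not np.isclose(sum(self.indel_length_probs), 1.0):
            raise ValueError("indel length probabilities must sum to 1")


def _draw_position(rng: np.random.Generator, windows: Sequence[CdsWindow]) -> int:
    widths = np.array([w.end - w.start + 1 for w in windows], dtype=float)
    wi = rng.choice(len(windows), p=widths / widths.sum())
    w = windows[wi]
    return int(rng.integers(w.start, w.end + 1))


def _draw_edit(
    rng: np.random.Generator, cds: str, config: SpectrumConfig
) -> EditCall:
    cat = rng.choice(
        ["SNV", "indel", "complex"],
        p=[config.p_snv, config.p_indel, config.p_complex],
    )
    pos = _draw_position(rng, config.windows)
    if cat == "SNV":
        ref = cds[pos - 1]
        alt = str(rng.choice(np.array([b for b in "ACGT" if b != ref])))
        return EditCall("SNV", pos, ref, alt)
    if cat == "indel":
        length = int(
            rng.choice(np.array(config.indel_lengths), p=config.indel_length_probs)
        )
        # left-normalize within repeat context so truth coordinates match
        # the VCF-style calls produced downstream
        if rng.random() < 0.5 and pos + length - 1 <= len(cds) - 3:
            p, allele = _left_shift("deletion", pos, cds[pos - 1 : pos - 1 + length], cds, 0)
            return EditCall("deletion", p, allele, "")
        ins = "".join(rng.choice(_BASES, size=length))
        p, allele = _left_shift("insertion", pos, ins, cds, 0)
        return EditCall("insertion", p, "", allele)
    # Complex: replace a 2-nt run with a 1- or 3-nt run drawn from bases
    # absent from the local context, so the event realigns as a single
    # mixed difference run rather than decomposing into SNV + indel.
    ref_len = 2
    alt_len = 1 if rng.random() < 0.5 else 3
    for _try in range(100):
        ref = cds[pos - 1 : pos - 1 + ref_len]
        context = cds[max(0, pos - 3) : pos - 1 + ref_len + 2]
        choices = [b for b in "ACGT" if b not in context]
        repeat_free = all(
            context[i] != context[i + 1] for i in range(len(context) - 1)
        )
        if choices and repeat_free and len(ref) == ref_len:
            break
        pos = _draw_position(rng, config.windows)
    else:
        pos = min(pos, len(cds) - 3 - ref_len)
        ref = cds[pos - 1 : pos - 1 + ref_len]
        choices = [b for b in "ACGT" if b not in ref]
    alt = "".join(str(rng.choice(np.array(choices))) for _ in range(alt_len))
    return EditCall("complex", pos, ref, alt)


def make_mutant_clones(
    cds: str,
    n: int,
    config: SpectrumConfig | None = None,
    edits_per_clone: int = 1,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate mutant clones from a configured spectrum, with truth.

    Each clone carries ``edits_per_clone`` primary edits (one by default,
    keeping truth consequences unambiguous) drawn from the category
    proportions, positioned in the configured CDS windows.  The truth
    table records (clone, kind, pos, ref, alt, consequence) where the
    consequence is classified from the generated edits directly —
    independently of the alignment-based calling path being tested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SpectrumConfig()
    cds = cds.upper()
    for w in config.windows:
        if w.end > len(cds):
            raise ValueError(f"window [{w.start},{w.end}] outside CDS of length {len(cds)}")
    rng = np.random.default_rng(config.seed)
    clones: list[SequenceRecord] = []
    rows = []
    for k in range(n):
        edits: list[EditCall] = []
        occupied: list[tuple[int, int]] = []
        while len(edits) < edits_per_clone:
            e = _draw_edit(rng, cds, config)
            span = (e.ref_pos - 2, e.ref_pos + max(1, len(e.ref_allele)) + 2)
            if any(s < span[1] and span[0] < t for s, t in occupied):
                continue
            edits.append(e)
            occupied.append(span)
        edits.sort(key=lambda e: e.ref_pos)
        mutant = apply_edits(cds, edits)
        cons = classify_consequence(edits, cds)
        clone_id = f"clone_{k:04d}"
        clones.append(SequenceRecord(clone_id, mutant))
        for e in edits:
            rows.append(
                dict(
                    clone=clone_id,
                    kind=e.kind,
                    pos=e.ref_pos,
                    ref=e.ref_allele,
                    alt=e.alt_allele,
                    consequence=cons.consequence_class,
                )
            )
    truth = pd.DataFrame(rows, columns=["clone", "kind", "pos", "ref", "alt", "consequence"])
    return clones, truth
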