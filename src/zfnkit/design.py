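"""Zinc-finger nuclease pair design.

A ZFN target site is a pair of 9-bp half-sites separated by a spacer where
the FokI domains dimerize.  Each half-site is read by a three-finger
zinc-finger protein (ZFP), one finger per 3-bp triplet, and each finger's
specificity is carried by a 7-residue recognition helix.  This module
selects candidate half-site pairs from a target sequence, assembles ZFP
amino-acid sequences from a recognition-helix table and a fixed assembly
grammar (constant N/C termini, finger backbone and inter-finger linker),
and reverse-translates them into codon-optimized DNA scored by the Codon
Adaptation Index (CAI) while avoiding restriction-site motifs used for
subcloning.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqio import reverse_complement

__all__ = [
    "HalfSite",
    "HelixTable",
    "AssemblyGrammar",
    "CodonUsageTable",
    "ZFNDesign",
    "DEFAULT_HELICES",
    "XBAI_SITE",
    "BAMHI_SITE",
    "select_half_site_pairs",
    "assemble_zfp",
    "compute_cai",
    "reverse_translate_optimize",
    "design_pair",
]

# Recognition helices for the six triplets used by the NF-YA8 ZFN pair.
DEFAULT_HELICES: dict[str, str] = {
    "GCT": "TSGELVR",
    "CTA": "QNSTLTE",
    "CCC": "SKKHLAE",
    "CTT": "TTGALTE",
    "ACG": "RTDTLRD",
    "AGG": "RSDHLTN",
}

XBAI_SITE = "TCTAGA"
BAMHI_SITE = "GGATCC"

# 61 sense codons of the standard genetic code, grouped by amino acid.
_SENSE_CODONS: dict[str, str] = dict(standard_dna_table.forward_table)
_STOP_CODONS: tuple[str, ...] = tuple(standard_dna_table.stop_codons)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_SENSE_CODONS.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class HalfSite:
    """A 9-bp half-site, written 5'->3' as bound by its ZFP."""

    sequence: str
    side: Literal["left", "right"] = "left"
    strand_bound: Literal["top", "bottom"] = "top"

    def __post_init__(self) -> None:
        if len(self.sequence) != 9:
            raise ValueError(
                f"half-site must be exactly 9 nt, got {len(self.sequence)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def triplets(self) -> tuple[str, str, str]:
        """The three 3-bp triplets, 5'->3'."""
        s = self.sequence
        return (s[0:3], s[3:6], s[6:9])


class HelixTable:
    """Mapping of 3-nt triplet -> 7-residue recognition helix."""

    def __init__(self, entries: Mapping[str, str] | None = None):
        self.entries: dict[str, str] = {}
        for trip, helix in (entries if entries is not None else DEFAULT_HELICES).items():
            trip = trip.upper()
            helix = helix.upper()
            if len(trip) != 3:
                raise ValueError(f"triplet '{trip}' is not 3 nt")
            if len(helix) != 7:
                raise ValueError(f"helix '{helix}' for {trip} is not 7 residues")
            self.entries[trip] = helix

    def __contains__(self, triplet: str) -> bool:
        return triplet.upper() in self.entries

    def __getitem__(self, triplet: str) -> str:
        return self.entries[triplet.upper()]

    def covers(self, half_site: HalfSite) -> bool:
        return all(t in self.entries for t in half_site.triplets)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "HelixTable":
        """Read a 2-column tab-delimited (TRIPLET, HELIX) file."""
        entries: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}: expected 2 tab-separated columns: {line!r}")
                entries[fields[0]] = fields[1]
        return cls(entries)


@dataclass(frozen=True)
class AssemblyGrammar:
    """Constant segments of a modular three-finger ZFP assembly."""

    n_terminus: str = "LEPGEKP"
    backbone_n: str = "YKCPECGKSFS"
    backbone_c: str = "HQRTH"
    linker: str = "TGEKP"
    c_terminus: str = "TGKKTS"

    @property
    def three_finger_length(self) -> int:
        finger = len(self.backbone_n) + 7 + len(self.backbone_c)
        return (
            len(self.n_terminus)
            + 3 * finger
            + 2 * len(self.linker)
            + len(self.c_terminus)
        )


class CodonUsageTable:
    """Codon usage frequencies and relative adaptiveness w.

    For each amino acid, w(codon) = frequency / max frequency among its
    synonymous codons, so the most-used codon has w = 1.  Codons absent
    from the supplied table receive a pseudo-count of 0.5 before w is
    computed, keeping every w strictly positive.  Stop codons are kept
    (for reverse translation of '*') but never enter CAI.
    """

    PSEUDOCOUNT = 0.5

    def __init__(self, frequencies: Mapping[str, float]):
        freqs = {c.upper().replace("U", "T"): float(f) for c, f in frequencies.items()}
        for codon, f in freqs.items():
            if f < 0:
                raise ValueError(f"negative frequency for codon {codon}")
        self.frequency: dict[str, float] = {}
        for codon in list(_SENSE_CODONS) + list(_STOP_CODONS):
            self.frequency[codon] = freqs.get(codon, 0.0) or self.PSEUDOCOUNT
        self.w: dict[str, float] = {}
        for aa, codons in _AA_TO_CODONS.items():
            m = max(self.frequency[c] for c in codons)
            for c in codons:
                self.w[c] = self.frequency[c] / m
        m = max(self.frequency[c] for c in _STOP_CODONS)
        for c in _STOP_CODONS:
            self.w[c] = self.frequency[c] / m

    @classmethod
    def equal_usage(cls) -> "CodonUsageTable":
        """A flat table (w = 1 everywhere); useful as a neutral default."""
        return cls({c: 1.0 for c in list(_SENSE_CODONS) + list(_STOP_CODONS)})

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CodonUsageTable":
        """Read a 2-column tab-delimited (CODON, FREQUENCY) file.

        Frequencies may be per-thousand or fractions; only within-family
        ratios matter for w, so no explicit normalization is needed.
        """
        freqs: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}: expected 2 tab-separated columns: {line!r}")
                freqs[fields[0]] = float(fields[1])
        return cls(freqs)

    def ranked_codons(self, aa: str) -> list[str]:
        """Synonymous codons for ``aa`` sorted by descending w, then alphabetically."""
        codons = _STOP_CODONS if aa == "*" else _AA_TO_CODONS.get(aa)
        if codons is None:
            raise ValueError(f"unknown amino acid {aa!r}")
        return sorted(codons, key=lambda c: (-self.w[c], c))


@dataclass
class ZFNDesign:
    """A complete paired design: half-sites, proteins, optimized CDS, CAI."""

    left: HalfSite
    right: HalfSite
    spacer_length: int
    left_protein: str = ""
    right_protein: str = ""
    left_cds: str = ""
    right_cds: str = ""
    cai_left: float = float("nan")
    cai_right: float = float("nan")


def select_half_site_pairs(
    seq: str,
    spacer_range: Iterable[int],
    helix_table: HelixTable,
) -> list[tuple[HalfSite, HalfSite, int, int]]:
    """Enumerate candidate (left, right, spacer, offset) target sites in ``seq``.

    The tail-to-tail FokI geometry places the left ZFP on the bottom
    strand: the top strand must read revcomp(left) + spacer + right.  A
    candidate is reported only when every triplet of both half-sites has a
    recognition helix in ``helix_table``.  Candidates are sorted by
    ascending offset, ties broken by smaller spacer.
    """
    spacers = sorted(set(int(s) for s in spacer_range))
    if not spacers:
        raise ValueError("spacer_range must be non-empty")
    if any(s < 0 for s in spacers):
        raise ValueError("spacer lengths must be >= 0")
    seq = seq.upper()
    candidates: list[tuple[HalfSite, HalfSite, int, int]] = []
    for offset in range(len(seq)):
        for spacer in spacers:
            end = offset + 18 + spacer
            if end > len(seq):
                continue
            left_top = seq[offset : offset + 9]
            right_top = seq[offset + 9 + spacer : end]
            if "N" in left_top or "N" in right_top:
                continue
            left = HalfSite(reverse_complement(left_top), side="left", strand_bound="bottom")
            right = HalfSite(right_top, side="right", strand_bound="top")
            if helix_table.covers(left) and helix_table.covers(right):
                candidates.append((left, right, spacer, offset))
    return candidates


def assemble_zfp(
    half_site: HalfSite,
    helix_table: HelixTable,
    grammar: AssemblyGrammar | None = None,
    finger_order: Literal["as_listed", "antiparallel"] = "as_listed",
) -> str:
    """Assemble a three-finger ZFP amino-acid sequence for a half-site.

    Each finger is backbone_n + recognition helix + backbone_c; fingers are
    joined by the linker and flanked by the constant N/C termini, giving
    92 aa for a three-finger array.

    ``finger_order`` sets the finger-to-triplet assignment: ``"as_listed"``
    assigns F1..F3 to the half-site triplets 5'->3'; ``"antiparallel"``
    assigns F1 to the 3'-most triplet (the structural convention for
    Cys2His2 arrays, whose N-terminal finger contacts the 3' end of the
    site).
    """
    grammar = grammar or AssemblyGrammar()
    triplets = list(half_site.triplets)
    if finger_order == "antiparallel":
        triplets.reverse()
    elif finger_order != "as_listed":
        raise ValueError(f"unknown finger_order {finger_order!r}")
    missing = [t for t in triplets if t not in helix_table]
    if missing:
        raise KeyError(
            f"no recognition helix for triplet(s) {', '.join(missing)} "
            f"of half-site {half_site.sequence}"
        )
    fingers = [
        grammar.backbone_n + helix_table[t] + grammar.backbone_c for t in triplets
    ]
    return grammar.n_terminus + grammar.linker.join(fingers) + grammar.c_terminus


def compute_cai(cds: str, table: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of w over informative codons.

    Codons for single-codon amino acids (ATG/Met, TGG/Trp) carry no
    choice and are excluded, as are stop codons; a terminal stop codon is
    permitted, an internal one is an error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    log_sum = 0.0
    n = 0
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
            continue
        if codon not in _SENSE_CODONS:
            raise ValueError(f"invalid codon {codon!r} at codon {i + 1}")
        if codon in ("ATG", "TGG"):
            continue
        log_sum += math.log(table.w[codon])
        n += 1
    if n == 0:
        return 1.0
    return math.exp(log_sum / n)


def _motif_violations(
    dna: str,
    motifs: Sequence[str],
    allowed_spans: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Occurrences of any motif (either strand) outside the allowed spans."""
    hits: list[tuple[int, int]] = []
    patterns = set()
    for m in motifs:
        m = m.upper()
        patterns.add(m)
        patterns.add(reverse_complement(m))
    for pat in sorted(patterns):
        start = dna.find(pat)
        while start != -1:
            span = (start, start + len(pat))
            if not any(a <= span[0] and span[1] <= b for a, b in allowed_spans):
                hits.append(span)
            start = dna.find(pat, start + 1)
    return sorted(set(hits))


def reverse_translate_optimize(
    protein: str,
    table: CodonUsageTable,
    forbidden_motifs: Sequence[str] = (XBAI_SITE, BAMHI_SITE),
    flank_5: str = XBAI_SITE,
    flank_3: str = BAMHI_SITE,
    max_window: int = 4,
) -> str:
    """Reverse-translate ``protein`` into CAI-maximal DNA avoiding motifs.

    Strategy: greedy per-codon choice of the highest-w codon (alphabetical
    tie-break), followed by local repair of forbidden-motif occurrences —
    at each violation, synonymous codon combinations within a sliding
    window (2 codons, widened up to ``max_window`` when stuck) are tried in
    order of decreasing CAI contribution until the violation disappears
    without creating a new one inside the examined region.  Motifs are
    checked on both strands over the full flanked sequence; the flanks
    themselves (typically the XbaI/BamHI subcloning sites) are exempt.

    Returns flank_5 + CDS + flank_3.  Raises ``RuntimeError`` naming the
    stuck codon window when no motif-free assignment is found.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    protein = protein.upper()
    flank_5 = flank_5.upper()
    flank_3 = flank_3.upper()
    ranked = [table.ranked_codons(aa) for aa in protein]
    codons = [r[0] for r in ranked]

    f5 = len(flank_5)
    n = len(protein)

    def full(codon_list: list[str]) -> str:
        return flank_5 + "".join(codon_list) + flank_3

    def allowed_spans(total_len: int) -> list[tuple[int, int]]:
        spans = []
        if flank_5:
            spans.append((0, f5))
        if flank_3:
            spans.append((total_len - len(flank_3), total_len))
        return spans

    def violations(codon_list: list[str]) -> list[tuple[int, int]]:
        dna = full(codon_list)
        return _motif_violations(dna, forbidden_motifs, allowed_spans(len(dna)))

    for _pass in range(4 * n + 4):
        viols = violations(codons)
        if not viols:
            break
        v_start, v_end = viols[0]
        # Codon indices overlapped by the violating occurrence.
        c_lo = max(0, (v_start - f5) // 3)
        c_hi = min(n - 1, (v_end - 1 - f5) // 3)
        width = max(2, c_hi - c_lo + 1)
        repaired = False
        while width <= max_window and not repaired:
            lo = max(0, min(c_lo, n - width))
            hi = min(n - 1, lo + width - 1)
            combos = itertools.product(*(ranked[i] for i in range(lo, hi + 1)))
            ranked_combos = sorted(
                combos,
                key=lambda cmb: (-sum(math.log(table.w[c]) for c in cmb), cmb),
            )
            for combo in ranked_combos:
                trial = list(codons)
                trial[lo : hi + 1] = combo
                t_viols = violations(trial)
                # Accept if this occurrence is gone and nothing new appears
                # in or around the repaired window.
                guard_lo = f5 + 3 * lo - 6
                guard_hi = f5 + 3 * (hi + 1) + 6
                if not any(
                    s < guard_hi and e > guard_lo for s, e in t_viols
                ) and len(t_viols) < len(viols) + 1:
                    codons = trial
                    repaired = True
                    break
            width += 1
        if not repaired:
            raise RuntimeError(
                f"could not remove forbidden motif at nt {v_start}-{v_end}: "
                f"stuck in codon window {c_lo + 1}-{c_hi + 1}"
            )
    else:
        raise RuntimeError("motif repair did not converge within the pass budget")

    result = full(codons)
    cds = "".join(codons)
    if str(Seq(cds).translate()) != protein:
        raise AssertionError("optimizer produced DNA that does not translate back")
    return result


def design_pair(
    left: HalfSite,
    right: HalfSite,
    spacer_length: int,
    helix_table: HelixTable | None = None,
    usage_table: CodonUsageTable | None = None,
    grammar: AssemblyGrammar | None = None,
    left_finger_order: Literal["as_listed", "antiparallel"] = "as_listed",
    right_finger_order: Literal["as_listed", "antiparallel"] = "antiparallel",
    forbidden_motifs: Sequence[str] = (XBAI_SITE, BAMHI_SITE),
    flank_5: str = XBAI_SITE,
    flank_3: str = BAMHI_SITE,
) -> ZFNDesign:
    """Assemble and codon-optimize both ZFPs of a pair into a ZFNDesign.

    The per-side finger-order defaults mirror the published NF-YA8 arrays,
    which list the left array's fingers 5'->3' and the right array's
    3'->5'.
    """
    helix_table = helix_table or HelixTable()
    usage_table = usage_table or CodonUsageTable.equal_usage()
    lp = assemble_zfp(left, helix_table, grammar, left_finger_order)
    rp = assemble_zfp(right, helix_table, grammar, right_finger_order)
    lflanked = reverse_translate_optimize(
        lp, usage_table, forbidden_motifs, flank_5, flank_3
    )
    rflanked = reverse_translate_optimize(
        rp, usage_table, forbidden_motifs, flank_5, flank_3
    )
    lcds = lflanked[len(flank_5) : len(lflanked) - len(flank_3)]
    rcds = rflanked[len(flank_5) : len(rflanked) - len(flank_3)]
    return ZFNDesign(
        left=left,
        right=right,
        spacer_length=spacer_length,
        left_protein=lp,
        right_protein=rp,
        left_cds=lcds,
        right_cds=rcds,
        cai_left=compute_cai(lcds, usage_table),
        cai_right=compute_cai(rcds, usage_table),
    )
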