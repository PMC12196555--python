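"""Genotyping of nuclease-induced edits from clone/amplicon sequences.

Each mutant clone sequence is globally aligned to the wild-type reference
CDS; maximal runs of difference columns become edit calls (SNV, insertion,
deletion, or complex for mixed runs); calls are projected to the protein
level (synonymous / missense / in-frame indel / frameshift / premature
stop); and a clone set is summarized as a mutation spectrum — the per-clone
proportions of SNV, indel and complex mutations plus the overlapping
frameshift and loss-of-function annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .seqio import SequenceRecord

__all__ = [
    "AlignScores",
    "PairwiseAlignment",
    "EditCall",
    "ConsequenceCall",
    "SpectrumSummary",
    "global_align",
    "call_edits",
    "apply_edits",
    "classify_consequence",
    "percent_identity",
    "summarize_spectrum",
    "genotype_clones",
]


@dataclass(frozen=True)
class AlignScores:
    """Affine-gap scores for global alignment of short amplicons.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings."""

    ref_aligned: str
    alt_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.alt_aligned):
            raise ValueError("aligned strings must have equal length")
        if any(
            r == "-" and a == "-"
            for r, a in zip(self.ref_aligned, self.alt_aligned)
        ):
            raise ValueError("alignment contains an all-gap column")


@dataclass(frozen=True)
class EditCall:
    """A single difference against the reference, on 1-based CDS coordinates.

    ``ref_pos`` is the first reference base of the call; for insertions it
    is the reference position AFTER which the bases are inserted (0 means
    before the first base).
    """

    kind: Literal["SNV", "insertion", "deletion", "complex"]
    ref_pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "SNV" and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise ValueError("SNV must have single-base alleles")
        if self.kind == "insertion" and self.ref_allele != "":
            raise ValueError("insertion must have empty ref allele")
        if self.kind == "deletion" and self.alt_allele != "":
            raise ValueError("deletion must have empty alt allele")

    @property
    def net_length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class ConsequenceCall:
    """Protein-level classification of a clone's edits."""

    consequence_class: Literal[
        "synonymous", "missense", "in_frame_indel", "frameshift", "premature_stop", "none"
    ]
    first_affected_codon: int
    last_intact_codon: int
    aa_change: str = ""
    frameshift: bool = False
    premature_stop: bool = False


@dataclass(frozen=True)
class SpectrumSummary:
    """Mutation-spectrum proportions over a clone set.

    SNV/indel/complex partition the mutated clones (they sum to 100% up to
    rounding); frameshift and loss-of-function are overlapping annotations
    computed from the protein-level consequences, not partition members.
    """

    n_sequences: int
    pct_snv: float
    pct_indel: float
    pct_complex: float
    pct_frameshift: float
    pct_lof: float
    n_unedited: int = 0


def global_align(ref: str, alt: str, scores: AlignScores | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    The first traceback of the aligner is taken, which is deterministic
    for fixed inputs and scores.
    """
    if not ref or not alt:
        raise ValueError("both sequences must be non-empty")
    scores = scores or AlignScores()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    aln = aligner.align(ref.upper(), alt.upper())[0]
    ref_aligned, alt_aligned = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ref_aligned, alt_aligned, float(aln.score))


def _left_shift(
    kind: str, pos: int, allele: str, ref: str, floor: int
) -> tuple[int, str]:
    """Left-align a pure indel within repeat context, not crossing ``floor``.

    For deletions ``pos`` is the 1-based first deleted base; for
    insertions the 1-based anchor base after which the insertion sits.
    """
    if kind == "deletion":
        while pos - 1 > floor and ref[pos - 2] == allele[-1]:
            allele = ref[pos - 2] + allele[:-1]
            pos -= 1
    elif kind == "insertion":
        while pos > floor and pos >= 1 and ref[pos - 1] == allele[-1]:
            allele = ref[pos - 1] + allele[:-1]
            pos -= 1
    return pos, allele


def call_edits(aln: PairwiseAlignment) -> list[EditCall]:
    """Convert an alignment into edit calls.

    Maximal runs of difference columns become one call each: a single
    substitution column is an SNV; a pure gap run is an insertion or
    deletion, left-aligned within homopolymer/repeat context; any mixed
    run (including adjacent substitutions) is a complex call.
    """
    ref = aln.ref_aligned.replace("-", "")
    calls: list[EditCall] = []
    runs: list[tuple[int, int]] = []  # column spans of difference runs
    in_run = False
    for col, (r, a) in enumerate(zip(aln.ref_aligned, aln.alt_aligned)):
        if r != a:
            if not in_run:
                runs.append((col, col + 1))
                in_run = True
            else:
                runs[-1] = (runs[-1][0], col + 1)
        else:
            in_run = False

    # Reference coordinate (number of ref bases consumed) before each column.
    ref_consumed = [0] * (len(aln.ref_aligned) + 1)
    for col, r in enumerate(aln.ref_aligned):
        ref_consumed[col + 1] = ref_consumed[col] + (r != "-")

    prev_run_end_ref = 0  # floor for left-shifting (ref coord, 1-based end)
    for c0, c1 in runs:
        ref_part = aln.ref_aligned[c0:c1].replace("-", "")
        alt_part = aln.alt_aligned[c0:c1].replace("-", "")
        if c1 - c0 == 1 and ref_part and alt_part:
            calls.append(EditCall("SNV", ref_consumed[c0] + 1, ref_part, alt_part))
            prev_run_end_ref = ref_consumed[c1]
        elif alt_part == "":
            pos, allele = _left_shift(
                "deletion", ref_consumed[c0] + 1, ref_part, ref, prev_run_end_ref
            )
            calls.append(EditCall("deletion", pos, allele, ""))
            prev_run_end_ref = ref_consumed[c1]
        elif ref_part == "":
            pos, allele = _left_shift(
                "insertion", ref_consumed[c0], alt_part, ref, prev_run_end_ref
            )
            calls.append(EditCall("insertion", pos, "", allele))
            prev_run_end_ref = ref_consumed[c1]
        else:
            calls.append(EditCall("complex", ref_consumed[c0] + 1, ref_part, alt_part))
            prev_run_end_ref = ref_consumed[c1]
    calls.sort(key=lambda e: (e.ref_pos, e.kind))
    return calls


def apply_edits(ref: str, edits: Sequence[EditCall]) -> str:
    """Apply edit calls to the reference, reconstructing the alternate sequence."""
    ordered = sorted(edits, key=lambda e: (e.ref_pos, 0 if e.kind == "insertion" else 1))
    out = []
    cursor = 0  # 0-based position in ref
    for e in ordered:
        if e.kind == "insertion":
            anchor = e.ref_pos  # insert after this many ref bases
            if anchor < cursor or anchor > len(ref):
                raise ValueError(f"insertion anchor {e.ref_pos} out of order or bounds")
            out.append(ref[cursor:anchor])
            out.append(e.alt_allele)
            cursor = anchor
        else:
            start = e.ref_pos - 1
            if start < cursor or start + len(e.ref_allele) > len(ref):
                raise ValueError(f"edit at {e.ref_pos} out of order or bounds")
            if ref[start : start + len(e.ref_allele)] != e.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {e.ref_pos}: "
                    f"expected {e.ref_allele!r}, found "
                    f"{ref[start:start + len(e.ref_allele)]!r}"
                )
            out.append(ref[cursor:start])
            out.append(e.alt_allele)
            cursor = start + len(e.ref_allele)
    out.append(ref[cursor:])
    return "".join(out)


def _translate(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def classify_consequence(edits: Sequence[EditCall], cds: str) -> ConsequenceCall:
    """Classify the protein-level consequence of a clone's edits.

    The edits are applied to the CDS and both sequences translated in
    frame from the start codon.  A net indel length not divisible by 3 is
    a frameshift; a stop codon appearing before the reference terminus is
    a loss-of-function (premature stop); otherwise the call is an in-frame
    indel, a missense change (reported as e.g. ``231A>V`` when a single
    codon is affected) or synonymous.
    """
    cds = cds.upper()
    ref_prot = _translate(cds)
    if "*" in ref_prot[:-1]:
        raise ValueError("reference CDS contains an internal stop codon")
    if not edits:
        return ConsequenceCall("none", 0, len(cds) // 3)
    for e in edits:
        bound = e.ref_pos + max(0, len(e.ref_allele)) - 1
        if e.ref_pos < 0 or bound > len(cds):
            raise ValueError(f"edit at position {e.ref_pos} outside CDS of length {len(cds)}")

    mutant = apply_edits(cds, edits)
    mut_prot = _translate(mutant)

    # First nucleotide whose codon can differ from the reference.
    first_pos = min(
        (e.ref_pos + 1 if e.kind == "insertion" else e.ref_pos) for e in edits
    )
    first_codon = ceil(first_pos / 3)
    last_intact = (first_pos - 1) // 3

    net = sum(e.net_length for e in edits)
    frameshift = net % 3 != 0

    # A stop codon anywhere before the mutant's own final codon is a new,
    # premature terminator; a terminal stop (even if earlier than the
    # reference's, as after an in-frame deletion) is not.
    mut_stop = mut_prot.find("*")
    premature = mut_stop != -1 and mut_stop < len(mut_prot) - 1

    aa_change = ""
    if frameshift:
        cls = "frameshift"
    elif premature:
        cls = "premature_stop"
    elif net != 0:
        cls = "in_frame_indel"
    elif mut_prot == ref_prot:
        cls = "synonymous"
    else:
        cls = "missense"
        diffs = [i for i, (r, a) in enumerate(zip(ref_prot, mut_prot)) if r != a]
        if len(diffs) == 1:
            i = diffs[0]
            aa_change = f"{i + 1}{ref_prot[i]}>{mut_prot[i]}"
    return ConsequenceCall(
        consequence_class=cls,
        first_affected_codon=first_codon,
        last_intact_codon=last_intact,
        aa_change=aa_change,
        frameshift=frameshift,
        premature_stop=premature,
    )


def percent_identity(aln: PairwiseAlignment, include_gap_columns: bool = True) -> float:
    """Percent identical columns; gap columns count in the denominator by default."""
    n_cols = len(aln.ref_aligned)
    if n_cols == 0:
        raise ValueError("zero-length alignment")
    ident = sum(
        r == a and r != "-" for r, a in zip(aln.ref_aligned, aln.alt_aligned)
    )
    if include_gap_columns:
        return 100.0 * ident / n_cols
    ungapped = sum(
        r != "-" and a != "-" for r, a in zip(aln.ref_aligned, aln.alt_aligned)
    )
    if ungapped == 0:
        raise ValueError("alignment has no ungapped columns")
    return 100.0 * ident / ungapped


def summarize_spectrum(
    per_clone: Sequence[tuple[Sequence[EditCall], ConsequenceCall]],
    counting: Literal["per_sequence", "per_mutation"] = "per_sequence",
    on_unedited: Literal["error", "report"] = "error",
) -> SpectrumSummary:
    """Summarize a clone set's mutation spectrum.

    ``per_sequence`` (default) assigns each clone one primary category by
    the precedence complex > indel > SNV; ``per_mutation`` tallies every
    individual call.  Frameshift and loss-of-function percentages are
    always per-clone annotations over the mutated clones.
    """
    if not per_clone:
        raise ValueError("empty clone set")
    n_unedited = sum(1 for edits, _c in per_clone if not edits)
    if n_unedited and on_unedited == "error":
        raise ValueError(
            f"{n_unedited} clone(s) identical to the reference; "
            "pass on_unedited='report' to include them"
        )
    mutated = [(e, c) for e, c in per_clone if e]
    if not mutated:
        return SpectrumSummary(0, 0.0, 0.0, 0.0, 0.0, 0.0, n_unedited)

    if counting == "per_sequence":
        n = len(mutated)
        cats = []
        for edits, _c in mutated:
            kinds = {e.kind for e in edits}
            if "complex" in kinds:
                cats.append("complex")
            elif "insertion" in kinds or "deletion" in kinds:
                cats.append("indel")
            else:
                cats.append("SNV")
        n_snv = cats.count("SNV")
        n_indel = cats.count("indel")
        n_complex = cats.count("complex")
        denom = n
    elif counting == "per_mutation":
        all_calls = [e for edits, _c in mutated for e in edits]
        n = len(mutated)
        n_snv = sum(e.kind == "SNV" for e in all_calls)
        n_indel = sum(e.kind in ("insertion", "deletion") for e in all_calls)
        n_complex = sum(e.kind == "complex" for e in all_calls)
        denom = len(all_calls)
    else:
        raise ValueError(f"unknown counting mode {counting!r}")

    n_fs = sum(c.frameshift for _e, c in mutated)
    n_lof = sum(c.premature_stop for _e, c in mutated)
    return SpectrumSummary(
        n_sequences=n,
        pct_snv=100.0 * n_snv / denom,
        pct_indel=100.0 * n_indel / denom,
        pct_complex=100.0 * n_complex / denom,
        pct_frameshift=100.0 * n_fs / len(mutated),
        pct_lof=100.0 * n_lof / len(mutated),
        n_unedited=n_unedited,
    )


def genotype_clones(
    reference: str,
    clones: Iterable[SequenceRecord],
    scores: AlignScores | None = None,
    counting: Literal["per_sequence", "per_mutation"] = "per_sequence",
    on_unedited: Literal["error", "report"] = "report",
) -> tuple[pd.DataFrame, SpectrumSummary]:
    """Full genotyping pipeline: align, call, classify, summarize.

    Returns a per-call table (clone, kind, pos, ref, alt, consequence,
    identity) and the spectrum summary over the clone set.
    """
    rows = []
    per_clone: list[tuple[list[EditCall], ConsequenceCall]] = []
    for rec in clones:
        aln = global_align(reference, rec.sequence, scores)
        edits = call_edits(aln)
        cons = classify_consequence(edits, reference)
        ident = percent_identity(aln)
        per_clone.append((edits, cons))
        if not edits:
            rows.append(
                dict(clone=rec.identifier, kind="none", pos=0, ref="", alt="",
                     consequence="none", identity=round(ident, 2))
            )
        for e in edits:
            rows.append(
                dict(clone=rec.identifier, kind=e.kind, pos=e.ref_pos,
                     ref=e.ref_allele, alt=e.alt_allele,
                     consequence=cons.consequence_class,
                     identity=round(ident, 2))
            )
    table = pd.DataFrame(
        rows, columns=["clone", "kind", "pos", "ref", "alt", "consequence", "identity"]
    )
    spectrum = summarize_spectrum(per_clone, counting=counting, on_unedited=on_unedited)
    return table, spectrum
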