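"""Design a ZFN pair for a target region.

Builds the published NF-YA8 half-site pair, assembles both three-finger
zinc-finger proteins from the seeded recognition-helix table, and
reverse-translates them into codon-optimized DNA flanked by XbaI/BamHI
subcloning sites.
"""

from zfnkit import (
    CodonUsageTable,
    HalfSite,
    HelixTable,
    design_pair,
    select_half_site_pairs,
)

# The exon-6 target region: revcomp(left half-site) + 7-nt spacer + right
# half-site on the top strand (tail-to-tail FokI geometry).
target = "GGGTAGAGC" + "ACGTACG" + "AGGACGCTT"

helices = HelixTable()  # seeded with the six published triplet->helix entries
candidates = select_half_site_pairs(target, spacer_range={5, 6, 7}, helix_table=helices)
print(f"{len(candidates)} candidate site(s) with full helix coverage")

left, right, spacer, offset = candidates[0]
print(f"left half-site  {left.sequence} (bound on the bottom strand)")
print(f"right half-site {right.sequence} (bound on the top strand)")
print(f"spacer {spacer} nt at offset {offset}")

# A usage table would normally come from a species codon-usage file
# (CodonUsageTable.from_tsv); a flat table makes every synonymous choice
# equivalent, so the optimizer's output is driven by motif avoidance only.
design = design_pair(left, right, spacer, helices, CodonUsageTable.equal_usage())
print(f"\nleft ZFP  ({len(design.left_protein)} aa): {design.left_protein}")
print(f"right ZFP ({len(design.right_protein)} aa): {design.right_protein}")
print(f"CAI left {design.cai_left:.3f}, right {design.cai_right:.3f}")
print(f"left CDS starts {design.left_cds[:21]}... ({len(design.left_cds)} nt)")
# The proteins are 92 aa: constant termini, three helix-bearing fingers and
# two linkers; CAI 1.0 means every codon is its amino acid's most-used one.
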