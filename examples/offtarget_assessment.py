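"""Inspect the off-target verdict for a guide against one non-target allele.

Plants a guide's target site into a non-target allele with three
PAM-proximal mismatches, then shows the placement the scanner finds, the
position-weighted divergence score, and the resulting safety reason.
"""

from hlako import ScoringParams, assess_allele
from hlako.hla_db import Allele, parse_allele_name

guide = "GACGCCGAGGATGGCCGTCA"
# same locus but mutated at guide positions 18-20 (PAM itself intact)
mutated = guide[:17] + "AGT"
non_target = Allele(
    name=parse_allele_name("A*91:01:01:01"),
    accession="SYNEX001",
    genomic="TTTACCTGA" + mutated + "TGG" + "CCATGATTC",
    coding=None,
)

params = ScoringParams()  # w(i) = i/20, theta = 2.0, k = 4
assessment = assess_allele(guide, non_target, params)
print(f"guide {guide} vs {assessment.allele_name}: reason = {assessment.reason}")
for site in assessment.sites:
    print(
        f"  placement {site.strand}@{site.offset}  PAM {site.pam}"
        f"  mismatches {sorted(site.mismatch_positions)}"
        f"  divergence {site.divergence:.2f} (theta {params.theta})"
    )
print(
    "Divergence sums w(i)=i/20 over mismatch positions; PAM-proximal "
    "mismatches weigh most, and a functional-PAM site needs divergence >= "
    "theta to be considered protected."
)
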