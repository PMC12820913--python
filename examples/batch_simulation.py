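"""Batch-evaluate guide-design capability over synthetic cell-line typings.

Generates one synthetic family per HLA Class I gene, samples cell lines
carrying two alleles of each gene, and runs the full battery per line: six
single-allele knockouts and three pan-gene (both-alleles) knockouts. The
summary mirrors how the method is benchmarked: how often at least one
viable guide exists, and the mean guide yield per run.
"""

from hlako import generate_cohort, run_batch
from hlako.simulation import MODE_PAN, MODE_SINGLE, TypingRecord

cohort = generate_cohort(seed=1, n_lines=8)
records = [
    TypingRecord(
        line_id=row["line_id"],
        alleles=tuple(row[c] for c in ("A1", "A2", "B1", "B2", "C1", "C2")),
    )
    for _, row in cohort.typings.iterrows()
]

summary = run_batch(records, cohort.db)
for mode in (MODE_SINGLE, MODE_PAN):
    s = summary.by_mode[mode]
    print(
        f"{mode:>6}: {s.n_success}/{s.n_runs} runs with >=1 guide "
        f"({100 * s.success_fraction:.1f}%), "
        f"{s.total_guides} guides total, mean {s.mean_guides_per_run:.2f}/run"
    )
print(
    "Pan-gene runs only exclude the other two genes' alleles, so they keep "
    "far more shared candidates than single-allele runs, which must spare "
    "the highly similar sibling allele."
)
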