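# Methods

## Problem and model

`hlako` designs spCas9 guides that discriminate between HLA Class I alleles
of one personal genotype. The biological model is deliberately minimal and
sequence-level: a guide cuts where its 20-nt spacer matches the genome
adjacent to a functional PAM, knockout requires the cut to disrupt coding
sequence, and allele specificity requires that no non-target allele of the
genotype present a cleavable site. No on-target activity model (Doench-style
scores), chromatin context, or genome-wide off-target scan outside the
entered alleles is included; the off-target universe is exactly the
non-selected alleles of the genotype the user enters.

## Candidate enumeration and coordinates

Candidates are 23-nt windows with PAM `NGG` on either strand. Coordinates
are 0-based plus-strand offsets of the window's leftmost base. The blunt cut
3 bp 5' of the PAM is recorded as the offset `c` such that the break lies
between genomic positions `c` and `c+1`: `window_start + 16` on the plus
strand, `window_start + 5` on the minus strand. All occurrences are kept at
enumeration, including overlapping windows and duplicate spacers;
de-duplication happens only when candidates are intersected across target
alleles, where identity is the 20-mer spacer string irrespective of strand
and position (the guide RNA is the same reagent wherever it binds).

Bases outside A/C/G/T are retained in loaded sequences but never match a
PAM or spacer pattern (`N` matches nothing); this is conservative for
design, since an uncertain base can neither create a candidate nor excuse
an off-target mismatch.

## Exon mapping and the cut-site rule

Exon intervals are always re-derived from the allele's own record pair by
greedy left-to-right chaining: repeatedly take the longest prefix of the
remaining coding sequence that occurs in the genomic sequence at or after
the previous exon's end (leftmost occurrence on ties). Matching is exact —
IMGT genomic and coding records of one allele are mutually consistent, so a
failure to chain is treated as a data error rather than silently aligned
around. A candidate passes the coding filter when its cut coordinate `c`
satisfies `a − slack ≤ c ≤ b − 1 + slack` for some exon `[a, b)`, with
`slack = 3` by default. The slack extends *outward* from the exon: a cut
slightly inside an intron near a boundary still damages the splice context,
while exon-internal cuts always pass. With several targets the rule must
hold in every target allele, since knockout has to succeed in all of them.

## Off-target filter

For each retained spacer and each non-target allele, every ungapped
placement on either strand with at most `k` mismatches is scored. Cleavage
is predicted iff the placement's 3-nt PAM context is functional and the
divergence `D = Σ w(i)` over mismatch positions (guide coordinate `i`,
1 = PAM-distal, 20 = PAM-proximal) is below θ. Per non-target allele the
verdict is `absent` (no placement), `pam_disrupted` (placements but no
functional PAM), `mismatch_divergent` (functional-PAM placements all with
`D ≥ θ`), or `cleaved`. A guide with any `cleaved` verdict is rejected;
otherwise it is `pam_based` when every verdict is `pam_disrupted`/`absent`
and `mismatch_based` otherwise. `absent` counts toward `pam_based` because
no binding is at least as safe as PAM loss, keeping exactly the two output
categories the method defines. With no non-target alleles the off-target
constraint is vacuous and everything surviving the coding filter is
reported `pam_based` (logged as such).

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `w(i)` | per-position mismatch weight, non-decreasing toward the PAM | `i/20` | the simplest monotone scheme honouring seed-region sensitivity; swappable for a published position-weight table via `ScoringParams.from_weight_table` |
| `θ` | retention threshold on `D` | 2.0 | requires roughly two PAM-proximal or several distal mismatches before a functional-PAM site is trusted to be protected — a conservative middle ground |
| `k` | mismatch search bound | 4 | beyond 4 mismatches a placement is treated as non-binding (`absent`) |
| `aga_functional` | whether literal `AGA` is a functional PAM | on | implemented as the method states it; the canonical alternative motif is NAG, so the rule is exposed as a switch |
| `slack` | cut-to-exon-boundary tolerance, nt | 3 | the stated boundary rule, with our outward closed-span convention fixed above |

The weight values, θ and `k` are not published for the reference
implementation, so exact guide counts on real releases depend on this
calibration; the defaults are fixed once here and exposed as configuration.

## Determinism and ordering

The engine contains no randomness. Databases preserve source-file order,
which also defines partial-name autocompletion ("first full match");
reports are sorted PAM-based first, then lexicographically by spacer;
homozygous genotype entries are de-duplicated after resolution and a
duplicated target imposes no constraint against itself. Re-running any
design with identical inputs and parameters is bit-identical.

## Synthetic data

The fixture generator emulates the one property of the real locus the
method exploits: near-identical alleles distinguished by point
differences. A family is a uniform-random backbone with a configured
exon/intron layout and fixed flanks, planted 23-nt `NGG` guide loci wholly
inside exons, and derived alleles differing only by planted substitutions —
a PAM break (`NGG → NCG`, constructed so it can never form `NGG` or `AGA`)
or spacer mismatches at chosen guide positions, all recorded in a truth
manifest together with the engine outcome each variant guarantees in its
pairwise genotype (target = backbone, non-target = variant carrier). One
technical guard: the first base of every internal intron is forced to
differ from the next exon's first base so greedy chaining recovers the
configured layout exactly. Batch cohorts pair one family per gene (two
PAM-break alleles and one mismatch allele beside each backbone) with
typings sampling two distinct alleles per gene.

The generator does **not** emulate allele phylogeny or linkage, indel
polymorphism, HLA-like GC content, or the density of real inter-allele
differences. Green tests on these families therefore establish correctness
of the machinery — enumeration, chaining, scoring, classification,
aggregation — not the guide yields real genotypes would produce; those
depend on the real release files and on the calibration noted above.

## Problem sizes

The shipped study conditions are desk-scale by design: families of 2–4
alleles with ~400–600 bp genomic sequence, cohorts of 24 synthetic cell
lines (216 design runs), 50 seeded families for truth recovery in the test
suite and 20 in the acceptance script, 1,000/500 random cases for the
oracle-equivalence checks. These sizes exercise every code path while
keeping the whole suite in seconds.

## Known limitations

- Ungapped off-target alignment only: no bulges, no gapped placements.
- Exon chaining is exact; alleles whose coding record disagrees with their
  genomic record fail loudly rather than being rescued by alignment.
- The `AGA` functional-PAM rule is honoured literally as specified even
  though it is biologically unusual; disable via `ScoringParams` if NAG-style
  behaviour is wanted.
- Off-target screening is restricted to the entered genotype, not the whole
  database or genome.
- Byte-identical database round-trips hold for uppercase, 60-column input
  (the IMGT convention); lowercase input is upper-cased on load.
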