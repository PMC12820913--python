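"""Deterministic synthetic allele families with ground-truthed polymorphisms.

Real HLA Class I alleles of one gene are near-identical sequences differing
by scattered substitutions; allele-specific guide design exploits exactly
those differences. This module emulates that structure at miniature scale:
a random gene backbone with a configurable exon/intron layout, a set of
planted 23-nt NGG guide loci placed wholly inside exons, and derived
alleles that differ from the backbone only by planted substitutions —
either a PAM-disrupting change (NGG -> NCG, which can be neither NGG nor
AGA) or protospacer mismatches at chosen guide positions.

Every family ships with a truth manifest: the planted variants and, per
variant allele, the guide the engine is expected to report (or reject) when
the backbone allele is targeted against that variant allele. Families are
written in the IMGT FASTA dialect with a reserved ``SYN`` accession prefix
so they can never be mistaken for real alleles, and regeneration from the
same config and seed is byte-identical.

What the generator does NOT emulate: real allele phylogeny and linkage,
indel polymorphism, GC-rich HLA base composition, and the sheer density of
inter-allele differences in the real locus. Passing tests on these families
therefore demonstrate the correctness of the machinery, not the guide
yields of real genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Optional

import numpy as np

from .hla_db import AlleleDB, HlaError, load_database
from .offtarget import (
    MISMATCH_BASED,
    PAM_BASED,
    REJECTED,
    ScoringParams,
    divergence_score,
)

BASES = "ACGT"
WINDOW = 23
_LOCUS_MARGIN = 2  # bases kept clear between a locus window and anything else


class GenerationError(HlaError):
    """The requested family cannot be hosted by the configured layout."""


@dataclass(frozen=True)
class FamilyConfig:
    """Recipe for one synthetic allele family.

    exon_layout
        ordered (exon_length, following_intron_length) pairs; the last
        intron length may be 0. A fixed flank is added at both ends.
    n_pam_snps
        number of PAM-disrupting substitutions to plant, one per locus,
        distributed round-robin over the derived alleles.
    protospacer_positions
        guide positions (1..20) of the protospacer substitutions planted
        together at one additional locus in one derived allele;
        ``n_protospacer_snps`` is its length.
    """

    gene_symbol: str = "A"
    n_alleles: int = 2
    exon_layout: tuple[tuple[int, int], ...] = ((120, 60), (150, 0))
    n_pam_snps: int = 1
    protospacer_positions: tuple[int, ...] = ()
    seed: int = 0
    flank: int = 25

    @property
    def n_protospacer_snps(self) -> int:
        return len(self.protospacer_positions)

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise GenerationError("a family needs at least 2 alleles")
        if not self.exon_layout:
            raise GenerationError("empty exon layout")
        for exon_len, intron_len in self.exon_layout:
            if exon_len < 1 or intron_len < 0:
                raise GenerationError("invalid exon/intron length")
        for exon_len, intron_len in self.exon_layout[:-1]:
            if intron_len < 1:
                raise GenerationError("internal introns must be >= 1 nt")
        if len(set(self.protospacer_positions)) != len(self.protospacer_positions):
            raise GenerationError("duplicate protospacer positions")
        for p in self.protospacer_positions:
            if not 1 <= p <= 20:
                raise GenerationError(f"protospacer position {p} outside 1..20")
        if self.genomic_length < WINDOW:
            raise GenerationError("total genomic length below one 23-nt window")

    @property
    def genomic_length(self) -> int:
        return 2 * self.flank + sum(e + i for e, i in self.exon_layout)

    @property
    def n_loci(self) -> int:
        planted = self.n_pam_snps + (1 if self.protospacer_positions else 0)
        return max(1, planted)  # always guarantee one exonic NGG site


@dataclass(frozen=True)
class Variant:
    """One planted substitution, in plus-strand genomic coordinates."""

    allele: str
    offset: int
    ref: str
    alt: str
    role: str  # "pam_break" or "protospacer_mismatch(<position>)"


@dataclass(frozen=True)
class ExpectedGuide:
    """An engine outcome the family guarantees, in a pairwise genotype.

    Running ``design`` with ``target`` as the knockout allele and
    ``non_target`` as the only other genotype member must report
    ``protospacer`` with class ``expected_class`` — or omit it entirely when
    ``expected_class`` is ``rejected``.
    """

    protospacer: str
    target: str
    non_target: str
    expected_class: str
    locus_window_start: int


@dataclass
class TruthManifest:
    gene_symbol: str
    allele_names: list[str]
    exon_intervals: list[tuple[int, int]]
    loci: list[int]  # window_start of each planted guide locus
    locus_guides: list[str]  # backbone protospacer at each locus
    variants: list[Variant]
    expected_guides: list[ExpectedGuide]
    theta: float
    k: int

    def to_dict(self) -> dict:
        return {
            "gene_symbol": self.gene_symbol,
            "allele_names": self.allele_names,
            "exon_intervals": [list(iv) for iv in self.exon_intervals],
            "loci": self.loci,
            "locus_guides": self.locus_guides,
            "variants": [vars(v) for v in self.variants],
            "expected_guides": [vars(g) for g in self.expected_guides],
            "theta": self.theta,
            "k": self.k,
        }


@dataclass
class Family:
    """Generated family: FASTA texts, manifest, and convenience loaders."""

    config: FamilyConfig
    gen_fasta: str
    nuc_fasta: str
    manifest: TruthManifest

    def load_db(self) -> AlleleDB:
        return load_database(StringIO(self.gen_fasta), StringIO(self.nuc_fasta))

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gen": out / "hla_gen.fasta",
            "nuc": out / "hla_nuc.fasta",
            "manifest": out / "manifest.json",
        }
        paths["gen"].write_text(self.gen_fasta)
        paths["nuc"].write_text(self.nuc_fasta)
        paths["manifest"].write_text(json.dumps(self.manifest.to_dict(), indent=2) + "\n")
        return paths


def _exon_intervals(config: FamilyConfig) -> list[tuple[int, int]]:
    pos = config.flank
    out = []
    for exon_len, intron_len in config.exon_layout:
        out.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return out


def _place_loci(config: FamilyConfig, exons: list[tuple[int, int]]) -> list[int]:
    """Non-overlapping 23-nt windows wholly inside exons, margin-spaced."""
    loci: list[int] = []
    for a, b in exons:
        start = a + _LOCUS_MARGIN
        while start + WINDOW <= b - _LOCUS_MARGIN and len(loci) < config.n_loci:
            loci.append(start)
            start += WINDOW + _LOCUS_MARGIN
    if len(loci) < config.n_loci:
        raise GenerationError(
            f"layout hosts only {len(loci)} guide loci, need {config.n_loci}"
        )
    return loci


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(len(choices)))]


def generate_family(
    config: FamilyConfig, params: Optional[ScoringParams] = None
) -> Family:
    """Build one synthetic family and its truth manifest.

    *params* (default :class:`ScoringParams`) supplies the weights and theta
    under which the manifest's expected classes are computed.
    """
    params = params or ScoringParams()
    rng = np.random.default_rng(config.seed)
    exons = _exon_intervals(config)
    loci = _place_loci(config, exons)
    n = config.genomic_length

    backbone = list(rng.choice(list(BASES), size=n))
    # plant one NGG guide window per locus (random N, fixed GG)
    for ws in loci:
        window = list(rng.choice(list(BASES), size=21)) + ["G", "G"]
        backbone[ws : ws + WINDOW] = window

    # splice-boundary guard: the first intron base must differ from the next
    # exon's first base, otherwise greedy coding->genomic chaining would
    # extend the exon match into the intron
    for (_, end), (next_start, _) in zip(exons, exons[1:]):
        if backbone[end] == backbone[next_start]:
            backbone[end] = _other_base(rng, backbone[next_start])

    ref_seq = "".join(backbone)
    names = [
        f"{config.gene_symbol}*{90 + i:02d}:01:01:01" for i in range(config.n_alleles)
    ]

    # assign planted roles round-robin over the derived alleles
    roles: list[tuple[str, int]] = [("pam", li) for li in range(config.n_pam_snps)]
    if config.protospacer_positions:
        roles.append(("mismatch", config.n_pam_snps))
    n_derived = config.n_alleles - 1
    per_allele_roles: list[list[tuple[str, int]]] = [[] for _ in range(n_derived)]
    for r_idx, role in enumerate(roles):
        per_allele_roles[r_idx % n_derived].append(role)

    variants: list[Variant] = []
    expected: list[ExpectedGuide] = []
    seqs = [ref_seq]
    for d, assigned in enumerate(per_allele_roles):
        seq = list(ref_seq)
        name = names[d + 1]
        for kind, li in assigned:
            ws = loci[li]
            guide = ref_seq[ws : ws + 20]
            if kind == "pam":
                off = ws + 21  # middle PAM G -> C: neither NGG nor AGA
                variants.append(
                    Variant(allele=name, offset=off, ref=seq[off], alt="C", role="pam_break")
                )
                seq[off] = "C"
                expected.append(
                    ExpectedGuide(
                        protospacer=guide,
                        target=names[0],
                        non_target=name,
                        expected_class=PAM_BASED,
                        locus_window_start=ws,
                    )
                )
            else:
                for p in sorted(config.protospacer_positions):
                    off = ws + p - 1
                    alt = _other_base(rng, seq[off])
                    variants.append(
                        Variant(
                            allele=name,
                            offset=off,
                            ref=seq[off],
                            alt=alt,
                            role=f"protospacer_mismatch({p})",
                        )
                    )
                    seq[off] = alt
                score = divergence_score(config.protospacer_positions, params)
                expected.append(
                    ExpectedGuide(
                        protospacer=guide,
                        target=names[0],
                        non_target=name,
                        expected_class=(
                            MISMATCH_BASED if score >= params.theta else REJECTED
                        ),
                        locus_window_start=ws,
                    )
                )
        seqs.append("".join(seq))

    gen_parts, nuc_parts = [], []
    for i, (name, seq) in enumerate(zip(names, seqs)):
        accession = f"SYN{config.gene_symbol}{config.seed % 10000:04d}{i:02d}"
        coding = "".join(seq[a:b] for a, b in exons)
        gen_parts.append(f">HLA:{accession} {name} {len(seq)} bp\n{_wrap(seq)}\n")
        nuc_parts.append(f">HLA:{accession} {name} {len(coding)} bp\n{_wrap(coding)}\n")

    manifest = TruthManifest(
        gene_symbol=config.gene_symbol,
        allele_names=names,
        exon_intervals=exons,
        loci=loci,
        locus_guides=[ref_seq[ws : ws + 20] for ws in loci],
        variants=variants,
        expected_guides=expected,
        theta=params.theta,
        k=params.k,
    )
    return Family(
        config=config,
        gen_fasta="".join(gen_parts),
        nuc_fasta="".join(nuc_parts),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# multi-gene cohorts for batch simulation


@dataclass
class Cohort:
    """Three synthetic gene families (A/B/C) plus sampled cell-line typings."""

    families: dict[str, Family]
    typings: "object"  # pandas.DataFrame, imported lazily
    db: AlleleDB = field(default=None)  # type: ignore[assignment]


DEFAULT_COHORT_LAYOUT = ((110, 60), (140, 55), (120, 0))


def generate_cohort(
    seed: int,
    n_lines: int = 24,
    n_alleles: int = 4,
    exon_layout: tuple[tuple[int, int], ...] = DEFAULT_COHORT_LAYOUT,
    params: Optional[ScoringParams] = None,
) -> Cohort:
    """One family per Class I gene and a table of synthetic cell-line typings.

    Each family carries two PAM-break alleles and one mismatch allele
    (PAM-proximal substitutions at guide positions 18-20) next to the
    backbone allele, so sampled genotypes exercise both specificity classes.
    Typings draw two distinct alleles per gene, uniformly.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    families: dict[str, Family] = {}
    for gene in ("A", "B", "C"):
        cfg = FamilyConfig(
            gene_symbol=gene,
            n_alleles=n_alleles,
            exon_layout=exon_layout,
            n_pam_snps=max(1, n_alleles - 2),
            protospacer_positions=(18, 19, 20),
            seed=int(rng.integers(2**31)),
        )
        families[gene] = generate_family(cfg, params)

    rows = []
    for i in range(n_lines):
        row = {"line_id": f"LINE{i:03d}"}
        for gene in ("A", "B", "C"):
            names = families[gene].manifest.allele_names
            pick = rng.choice(len(names), size=2, replace=False)
            row[f"{gene}1"], row[f"{gene}2"] = names[pick[0]], names[pick[1]]
        rows.append(row)
    typings = pd.DataFrame(rows, columns=["line_id", "A1", "A2", "B1", "B2", "C1", "C2"])

    gen = "".join(f.gen_fasta for f in families.values())
    nuc = "".join(f.nuc_fasta for f in families.values())
    db = load_database(StringIO(gen), StringIO(nuc))
    return Cohort(families=families, typings=typings, db=db)
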