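"""Loading, indexing and name resolution for IPD-IMGT/HLA-style allele collections.

The IMGT distribution ships two FASTA files per release: ``hla_gen.fasta``
(full genomic sequences) and ``hla_nuc.fasta`` (spliced coding sequences),
both with headers of the form::

    >HLA:HLA00001 A*01:01:01:01 3503 bp

This module parses that dialect, pairs genomic and coding records by allele
name, and resolves user-supplied (possibly partial) WHO-nomenclature allele
names against the collection, autocompleting a partial name to the first
full match in source-file order.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: HLA Class I genes handled by this package.
CLASS_I_GENES = ("A", "B", "C")

#: WHO nomenclature expression suffixes (null, low, secreted, cytoplasmic,
#: aberrant, questionable).
_EXPRESSION_SUFFIXES = "NLSCAQ"

_HEADER_RE = re.compile(r"^HLA:(\S+)\s+(\S+)\s+(\d+)\s+bp$")


class HlaError(Exception):
    """Base class for errors raised by this package."""


class AlleleNameError(HlaError):
    """Malformed WHO-nomenclature allele name."""


class DatabaseLoadError(HlaError):
    """FASTA record could not be interpreted as an IMGT-dialect allele entry."""


class MissingAlleleError(HlaError):
    """No allele in the database matches the requested (partial) name."""


class SequenceUnavailableError(HlaError):
    """The allele exists but lacks the coding sequence needed for design."""


@dataclass(frozen=True)
class AlleleName:
    """A structured WHO-nomenclature HLA allele name.

    ``fields`` holds the 1-4 colon-separated numeric fields (allele group,
    protein, synonymous substitutions, non-coding differences); ``suffix``
    an optional expression letter; ``raw`` the text as entered.
    """

    gene: str
    fields: tuple[int, ...]
    suffix: Optional[str] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if self.gene not in CLASS_I_GENES:
            raise AlleleNameError(
                f"unsupported gene {self.gene!r}: only HLA Class I genes "
                f"{'/'.join(CLASS_I_GENES)} are accepted"
            )
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele name needs 1-4 numeric fields, got {len(self.fields)}"
            )

    def render(self) -> str:
        """Normalised ``GENE*ff:ff[:ff[:ff]][suffix]`` form."""
        body = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.gene}*{body}{self.suffix or ''}"

    def is_prefix_of(self, other: "AlleleName") -> bool:
        """True when this (possibly partial) name's leading fields match *other*."""
        return (
            self.gene == other.gene
            and len(self.fields) <= len(other.fields)
            and other.fields[: len(self.fields)] == self.fields
        )


def parse_allele_name(text: str) -> AlleleName:
    """Parse WHO nomenclature such as ``A*02:01`` or ``HLA-A*02:01:01:01``.

    Raises :class:`AlleleNameError` naming the offending token when the text
    is not a Class I allele name.
    """
    if not text or not text.strip():
        raise AlleleNameError("empty allele name")
    raw = text.strip()
    body = raw[4:] if raw.upper().startswith("HLA-") else raw
    if "*" not in body:
        raise AlleleNameError(f"missing '*' separator in {raw!r}")
    gene, _, rest = body.partition("*")
    gene = gene.upper()
    if not rest:
        raise AlleleNameError(f"no fields after '*' in {raw!r}")
    suffix = None
    if rest[-1].upper() in _EXPRESSION_SUFFIXES and not rest[-1].isdigit():
        suffix = rest[-1].upper()
        rest = rest[:-1]
    parts = rest.split(":")
    fields = []
    for part in parts:
        if not part.isdigit():
            raise AlleleNameError(f"non-numeric field {part!r} in {raw!r}")
        fields.append(int(part))
    return AlleleName(gene=gene, fields=tuple(fields), suffix=suffix, raw=raw)


@dataclass(frozen=True)
class ExonInterval:
    """Half-open genomic interval [start, end) of exon number ``ordinal``."""

    start: int
    end: int
    ordinal: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate exon interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class Allele:
    """One allele entry: name, accession and its genomic/coding sequences.

    ``coding`` is ``None`` for alleles present in the genomic file only; such
    alleles cannot be used as design targets. ``exons`` is filled lazily by
    the exon-mapping step. The original FASTA header lines are retained so a
    loaded database re-serialises byte-identically.
    """

    name: AlleleName
    accession: str
    genomic: str
    coding: Optional[str] = None
    exons: Optional[tuple[ExonInterval, ...]] = None
    gen_header: str = ""
    nuc_header: str = ""

    @property
    def full_name(self) -> str:
        return self.name.render()

    @property
    def usable(self) -> bool:
        """Whether the allele can serve in design (both sequences present)."""
        return bool(self.genomic) and bool(self.coding)


@dataclass
class AlleleDB:
    """Ordered allele collection with a name index.

    Order is the source-file order of the genomic FASTA, which defines the
    "first full match" used by partial-name autocompletion.
    """

    alleles: list[Allele] = field(default_factory=list)
    index: dict[str, Allele] = field(default_factory=dict)

    def add(self, allele: Allele) -> None:
        key = allele.full_name
        if key in self.index:
            raise DatabaseLoadError(f"duplicate allele name {key}")
        self.alleles.append(allele)
        self.index[key] = allele

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, full_name: str) -> bool:
        return full_name in self.index

    def get(self, full_name: str) -> Optional[Allele]:
        return self.index.get(full_name)


@dataclass(frozen=True)
class Resolution:
    """Result of resolving a user-entered name: the allele plus a flag that
    autocompletion occurred (callers must surface it for confirmation)."""

    allele: Allele
    autocompleted: bool


def _parse_header(description: str, record_no: int) -> tuple[str, AlleleName, int]:
    m = _HEADER_RE.match(description.strip())
    if not m:
        raise DatabaseLoadError(
            f"record {record_no}: unparseable header {description!r}"
        )
    accession, name_text, length = m.group(1), m.group(2), int(m.group(3))
    try:
        name = parse_allele_name(name_text)
    except AlleleNameError as exc:
        raise DatabaseLoadError(f"record {record_no}: {exc}") from exc
    return accession, name, length


def _read_records(source, what: str) -> list[tuple[str, AlleleName, str, str]]:
    """Yield (accession, name, sequence, header) per FASTA record."""
    out = []
    for i, rec in enumerate(SeqIO.parse(source, "fasta"), start=1):
        accession, name, declared = _parse_header(rec.description, i)
        seq = str(rec.seq).upper()
        if len(seq) != declared:
            logger.warning(
                "%s record %d (%s): sequence length %d != declared %d bp; keeping",
                what, i, name.render(), len(seq), declared,
            )
        out.append((accession, name, seq, rec.description))
    return out


PathOrHandle = Union[str, Path, io.TextIOBase]


def load_database(gen_fasta: PathOrHandle, nuc_fasta: PathOrHandle) -> AlleleDB:
    """Load paired genomic/coding FASTA files into an :class:`AlleleDB`.

    Alleles present in the genomic file but absent from the coding file are
    kept with ``coding=None`` and flagged unusable for design; coding-only
    records are dropped with a warning. Duplicate full names are an error.
    """
    gen_records = _read_records(gen_fasta, "gen")
    nuc_records = _read_records(nuc_fasta, "nuc")

    nuc_by_name: dict[str, tuple[str, str]] = {}
    for accession, name, seq, header in nuc_records:
        key = name.render()
        if key in nuc_by_name:
            raise DatabaseLoadError(f"duplicate allele name {key} in coding FASTA")
        nuc_by_name[key] = (seq, header)

    db = AlleleDB()
    for accession, name, seq, header in gen_records:
        coding, nuc_header = nuc_by_name.pop(name.render(), (None, ""))
        if coding is None:
            logger.warning(
                "allele %s has no coding sequence; unusable for design",
                name.render(),
            )
        db.add(
            Allele(
                name=name,
                accession=accession,
                genomic=seq,
                coding=coding,
                gen_header=header,
                nuc_header=nuc_header,
            )
        )
    for leftover in nuc_by_name:
        logger.warning("coding-only record %s ignored (no genomic sequence)", leftover)
    return db


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_database(db: AlleleDB, gen_fasta: PathOrHandle, nuc_fasta: PathOrHandle) -> None:
    """Re-serialise a database in the IMGT FASTA dialect (60-column wrap).

    For uppercase 60-column input (the distribution convention) this is the
    byte-identical inverse of :func:`load_database`.
    """

    def _dump(target, records: Iterable[tuple[str, str]]) -> None:
        own = isinstance(target, (str, Path))
        handle = open(target, "w") if own else target
        try:
            for header, seq in records:
                handle.write(f">{header}\n{_wrap(seq)}\n")
        finally:
            if own:
                handle.close()

    _dump(gen_fasta, ((a.gen_header, a.genomic) for a in db.alleles))
    _dump(
        nuc_fasta,
        (
            (a.nuc_header, a.coding)
            for a in db.alleles
            if a.coding is not None and a.nuc_header
        ),
    )


def resolve(partial: Union[str, AlleleName], db: AlleleDB) -> Resolution:
    """Resolve a (possibly partial) allele name against the database.

    A full name present in the database resolves to itself; otherwise the
    first allele in source order whose leading fields equal the partial's
    fields is returned with ``autocompleted=True``.

    Raises :class:`MissingAlleleError` when nothing matches and
    :class:`SequenceUnavailableError` when the match lacks a coding sequence.
    """
    name = parse_allele_name(partial) if isinstance(partial, str) else partial
    hit = db.get(name.render())
    autocompleted = False
    if hit is None:
        for allele in db.alleles:
            if name.is_prefix_of(allele.name):
                hit = allele
                autocompleted = True
                break
    if hit is None:
        raise MissingAlleleError(f"no allele matching {name.raw or name.render()}")
    if hit.coding is None:
        raise SequenceUnavailableError(
            f"{hit.full_name} has no coding sequence and cannot be used"
        )
    return Resolution(allele=hit, autocompleted=autocompleted)


def with_exons(allele: Allele, exons: Sequence[ExonInterval]) -> Allele:
    """Return a copy of *allele* carrying derived exon intervals."""
    return replace(allele, exons=tuple(exons))
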