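"""spCas9 candidate site enumeration and exon-aware cut-site filtering.

A candidate target site is a 23-nt window: a 20-nt protospacer followed by
the spCas9 PAM ``NGG``, read 5'->3' on either strand. The blunt Cas9 cut
falls between protospacer positions 17 and 18 (3 bp 5' of the PAM); in
plus-strand genomic coordinates the cut coordinate ``c`` means the break
lies between genomic positions ``c`` and ``c+1``.

Exon structure is re-derived from the allele's own sequences by greedy
longest-prefix chaining of the coding sequence onto the genomic sequence;
knockout guides must cut inside coding sequence (or within a small slack of
an exon boundary) so that repair indels disrupt the reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hla_db import ExonInterval, HlaError

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class ExonMappingError(HlaError):
    """Coding sequence is not an ordered concatenation of genomic substrings."""


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware; unknown characters pass through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CandidateSite:
    """One 23-nt spCas9 target window on a specific strand.

    ``window_start`` is the 0-based plus-strand offset of the window's
    leftmost base. On ``+`` the protospacer occupies the first 20 bases of
    the window and the cut coordinate is ``window_start + 16``; on ``-`` the
    plus strand reads ``CCN`` + revcomp(protospacer) and the cut coordinate
    is ``window_start + 5``.
    """

    protospacer: str
    pam: str
    strand: str
    window_start: int
    cut: int


def enumerate_sites(genomic: str) -> list[CandidateSite]:
    """Every NGG-adjacent 20-mer on both strands of *genomic*.

    All occurrences are recorded, including duplicate protospacer sequences
    and overlapping windows; output is sorted by (window_start, strand).
    Sequences shorter than 23 nt yield an empty list. Characters outside
    A/C/G/T never satisfy the PAM pattern.
    """
    sites: list[CandidateSite] = []
    n = len(genomic)
    for ws in range(n - 22):
        # plus strand: PAM GG at window positions 21-22
        if genomic[ws + 21] == "G" and genomic[ws + 22] == "G":
            sites.append(
                CandidateSite(
                    protospacer=genomic[ws : ws + 20],
                    pam=genomic[ws + 20 : ws + 23],
                    strand="+",
                    window_start=ws,
                    cut=ws + 16,
                )
            )
        # minus strand: CCN on the plus strand at the window's left edge
        if genomic[ws] == "C" and genomic[ws + 1] == "C":
            sites.append(
                CandidateSite(
                    protospacer=revcomp(genomic[ws + 3 : ws + 23]),
                    pam=revcomp(genomic[ws : ws + 3]),
                    strand="-",
                    window_start=ws,
                    cut=ws + 5,
                )
            )
    sites.sort(key=lambda s: (s.window_start, s.strand))
    return sites


def map_exons(genomic: str, coding: str) -> list[ExonInterval]:
    """Chain the coding sequence onto the genomic sequence as ordered exons.

    Greedy left-to-right: repeatedly take the longest prefix of the
    remaining coding sequence that occurs in the genomic sequence at or
    after the previous exon's end (leftmost occurrence on ties), emit it as
    the next exon, and advance. Succeeds iff the whole coding sequence is
    consumed; otherwise raises :class:`ExonMappingError` naming the first
    unmatched coding offset.
    """
    if not genomic or not coding:
        raise ExonMappingError("empty sequence")
    exons: list[ExonInterval] = []
    g = 0  # genomic cursor: exons may start at or after this offset
    c = 0  # coding cursor
    ordinal = 1
    while c < len(coding):
        if genomic.find(coding[c], g) == -1:
            raise ExonMappingError(
                f"coding offset {c}: no occurrence of the remaining coding "
                f"sequence in the genomic sequence after offset {g}"
            )
        # longest matchable prefix length, by bisection (occurrence of a
        # length-L prefix implies occurrence of every shorter prefix)
        lo, hi, best = 1, len(coding) - c, 1
        while lo <= hi:
            mid = (lo + hi) // 2
            if genomic.find(coding[c : c + mid], g) != -1:
                best = mid
                lo = mid + 1
            else:
                hi = mid - 1
        pos = genomic.find(coding[c : c + best], g)
        exons.append(ExonInterval(start=pos, end=pos + best, ordinal=ordinal))
        g = pos + best
        c += best
        ordinal += 1
    return exons


def cut_in_coding(site: CandidateSite, exons: list[ExonInterval], slack: int = 3) -> bool:
    """Whether the site's cut lies in an exon or within *slack* nt of a boundary.

    For an exon [a, b) the test is ``a - slack <= cut <= b - 1 + slack``:
    cuts inside the exon always pass, cuts just outside pass when within
    *slack* bases of either boundary.
    """
    return any(e.start - slack <= site.cut <= e.end - 1 + slack for e in exons)
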