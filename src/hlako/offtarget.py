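"""Off-target assessment of candidate guides against non-target HLA alleles.

A candidate guide is predicted to cleave a non-target allele when an
ungapped placement of its 20-mer exists there (within a mismatch tolerance)
whose 3-nt PAM context is functional (``NGG``, or literally ``AGA``) and
whose position-weighted mismatch divergence falls below a retention
threshold. Mismatches are weighted by guide position with PAM-proximal
positions heaviest, reflecting Cas9's seed-region sensitivity: a
PAM-proximal mismatch disrupts cleavage far more than a PAM-distal one, so
the divergence score measures how confidently mismatches protect the
non-target allele.

Per non-target allele the outcome is one of four reasons:

``absent``
    no placement within tolerance — the guide cannot bind at all;
``pam_disrupted``
    placements exist but none retains a functional PAM — cleavage is
    impossible regardless of spacer homology;
``mismatch_divergent``
    some placement keeps a functional PAM, but every such placement is
    divergent enough (score >= theta) to predict no cleavage;
``cleaved``
    some placement has a functional PAM and too little divergence — the
    guide is predicted to cut this allele and must be rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .guide_design import revcomp
from .hla_db import Allele

logger = logging.getLogger(__name__)

GUIDE_LEN = 20

# specificity classes / per-allele reasons
PAM_BASED = "pam_based"
MISMATCH_BASED = "mismatch_based"
REJECTED = "rejected"
REASON_ABSENT = "absent"
REASON_PAM_DISRUPTED = "pam_disrupted"
REASON_MISMATCH_DIVERGENT = "mismatch_divergent"
REASON_CLEAVED = "cleaved"

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _linear_weights() -> tuple[float, ...]:
    return tuple(i / GUIDE_LEN for i in range(1, GUIDE_LEN + 1))


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the off-target filter.

    weights
        ``weights[i-1]`` is the penalty w(i) of a mismatch at guide position
        i (1 = PAM-distal 5' end, 20 = PAM-proximal). Must be non-negative
        and non-decreasing. Default is the linear scheme w(i) = i/20.
    theta
        retention threshold: a functional-PAM site with divergence >= theta
        is considered protected by its mismatches. Default 2.0.
    k
        maximum mismatches searched; placements with more are treated as
        non-binding. Default 4.
    aga_functional
        whether the literal PAM ``AGA`` counts as functional alongside NGG.
    """

    weights: tuple[float, ...] = field(default_factory=_linear_weights)
    theta: float = 2.0
    k: int = 4
    aga_functional: bool = True

    def __post_init__(self) -> None:
        if len(self.weights) != GUIDE_LEN:
            raise ValueError(f"need {GUIDE_LEN} weights, got {len(self.weights)}")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if any(a > b for a, b in zip(self.weights, self.weights[1:])):
            raise ValueError("weights must be non-decreasing toward the PAM")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @classmethod
    def from_weight_table(cls, path, **kwargs) -> "ScoringParams":
        """Load w(1..20) from a whitespace/newline-separated text file."""
        values = [float(tok) for tok in open(path).read().split()]
        return cls(weights=tuple(values), **kwargs)


@dataclass(frozen=True)
class OffTargetSite:
    """One placement of a guide on a non-target allele.

    ``offset`` is the 0-based plus-strand offset of the aligned 20-mer's
    leftmost base; ``aligned_seq`` and ``pam`` are read in guide
    orientation; ``mismatch_positions`` uses guide coordinates 1..20
    (20 = PAM-proximal).
    """

    allele_name: str
    strand: str
    offset: int
    aligned_seq: str
    pam: str
    mismatch_positions: frozenset[int]
    divergence: float


@dataclass(frozen=True)
class AlleleAssessment:
    """Verdict for one non-target allele: its candidate off-target sites and
    the safety reason (or ``cleaved``)."""

    allele_name: str
    sites: tuple[OffTargetSite, ...]
    reason: str


def pam_functional(pam: str, aga_functional: bool = True) -> bool:
    """Whether a 3-nt PAM context supports spCas9 cleavage (NGG, or AGA)."""
    if len(pam) != 3:
        raise ValueError(f"PAM must be 3 nt, got {pam!r}")
    if pam[1] == "G" and pam[2] == "G":
        return True
    return aga_functional and pam == "AGA"


def divergence_score(
    mismatch_positions: Iterable[int], params: Optional[ScoringParams] = None
) -> float:
    """Position-weighted mismatch score: sum of w(i) over mismatch positions."""
    params = params or ScoringParams()
    total = 0.0
    for i in mismatch_positions:
        if not 1 <= i <= GUIDE_LEN:
            raise ValueError(f"mismatch position {i} outside 1..{GUIDE_LEN}")
        total += params.weights[i - 1]
    return total


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_sites(
    guide: str,
    allele: Allele,
    k: int,
    params: Optional[ScoringParams] = None,
) -> list[OffTargetSite]:
    """All ungapped placements of *guide* on either strand of *allele*.

    Returns every placement with at most *k* mismatches, each with its 3-nt
    PAM context read in guide orientation; placements whose PAM context
    would run off the sequence end are skipped. Positions where either base
    is outside A/C/G/T count as mismatches (N matches nothing). Sorted by
    (offset, strand). *params* only supplies the divergence weights.
    """
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    params = params or ScoringParams()
    genomic = allele.genomic
    n = len(genomic)
    if n < GUIDE_LEN:
        return []

    arr = _encode(genomic)
    arr_valid = np.isin(arr, _ACGT)
    windows = sliding_window_view(arr, GUIDE_LEN)
    windows_valid = sliding_window_view(arr_valid, GUIDE_LEN)

    sites: list[OffTargetSite] = []
    for strand in "+-":
        probe = guide if strand == "+" else revcomp(guide)
        q = _encode(probe)
        q_valid = np.isin(q, _ACGT)
        mm = (windows != q) | ~windows_valid | ~q_valid
        hits = np.nonzero(mm.sum(axis=1) <= k)[0]
        for o in hits.tolist():
            if strand == "+":
                if o + GUIDE_LEN + 3 > n:
                    continue
                pam = genomic[o + GUIDE_LEN : o + GUIDE_LEN + 3]
                aligned = genomic[o : o + GUIDE_LEN]
                positions = frozenset(
                    int(j) + 1 for j in np.nonzero(mm[o])[0]
                )
            else:
                if o < 3:
                    continue
                pam = revcomp(genomic[o - 3 : o])
                aligned = revcomp(genomic[o : o + GUIDE_LEN])
                positions = frozenset(
                    GUIDE_LEN - int(j) for j in np.nonzero(mm[o])[0]
                )
            sites.append(
                OffTargetSite(
                    allele_name=allele.full_name,
                    strand=strand,
                    offset=o,
                    aligned_seq=aligned,
                    pam=pam,
                    mismatch_positions=positions,
                    divergence=divergence_score(positions, params),
                )
            )
    sites.sort(key=lambda s: (s.offset, s.strand))
    return sites


def assess_allele(
    guide: str, allele: Allele, params: Optional[ScoringParams] = None
) -> AlleleAssessment:
    """Locate near-matching sites in one non-target allele and assign a reason."""
    params = params or ScoringParams()
    sites = find_sites(guide, allele, params.k, params)
    functional = [
        s for s in sites if pam_functional(s.pam, params.aga_functional)
    ]
    if not sites:
        reason = REASON_ABSENT
    elif not functional:
        reason = REASON_PAM_DISRUPTED
    elif any(s.divergence < params.theta for s in functional):
        reason = REASON_CLEAVED
    else:
        reason = REASON_MISMATCH_DIVERGENT
    return AlleleAssessment(
        allele_name=allele.full_name, sites=tuple(sites), reason=reason
    )


def classify_guide(assessments: Sequence[AlleleAssessment]) -> str:
    """Specificity class from the per-non-target assessments.

    ``rejected`` if any allele is predicted cleaved; ``pam_based`` when every
    allele is cleared by PAM loss or absence of binding; ``mismatch_based``
    when at least one allele keeps a functional PAM and is cleared only by
    mismatch divergence. An empty assessment list (no non-targets entered)
    is vacuously ``pam_based``.
    """
    if not assessments:
        logger.info("no non-target alleles: guide vacuously specific")
        return PAM_BASED
    reasons = {a.reason for a in assessments}
    if REASON_CLEAVED in reasons:
        return REJECTED
    if reasons <= {REASON_PAM_DISRUPTED, REASON_ABSENT}:
        return PAM_BASED
    return MISMATCH_BASED
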