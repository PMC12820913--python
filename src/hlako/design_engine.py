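"""End-to-end allele-specific guide design.

Pipeline: resolve the entered genotype, enumerate NGG candidate windows in
every target allele, derive each target's exon structure and keep sites
cutting in coding sequence, intersect candidate protospacers across
targets, assess each survivor against every non-target allele of the
genotype, classify (PAM-based vs mismatch-based), and report. The engine is
fully deterministic: fixed inputs and parameters give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .guide_design import CandidateSite, cut_in_coding, enumerate_sites, map_exons
from .hla_db import Allele, AlleleDB, ExonInterval, HlaError, resolve, with_exons
from .offtarget import (
    MISMATCH_BASED,
    PAM_BASED,
    REJECTED,
    AlleleAssessment,
    ScoringParams,
    assess_allele,
    classify_guide,
)

logger = logging.getLogger(__name__)

#: fixed TSV column order of the report table
TSV_COLUMNS = ("protospacer", "pams", "class", "target_sites", "offtargets")


class RequestError(HlaError):
    """Invalid genotype request (size, empty targets, targets not entered)."""


@dataclass(frozen=True)
class GenotypeRequest:
    """A personal Class I genotype (1-6 allele names) and the subset chosen
    for knockout. Names may be partial; they are resolved against the
    database at design time."""

    alleles: tuple[str, ...]
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise RequestError(
                f"a genotype holds 1-6 alleles, got {len(self.alleles)}"
            )
        if not self.targets:
            raise RequestError("no target allele selected for knockout")
        missing = set(self.targets) - set(self.alleles)
        if missing:
            raise RequestError(
                f"targets not part of the entered genotype: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GuideReport:
    """One surviving guide: its protospacer, the sites realising it in each
    target allele, its specificity class and the per-non-target verdicts."""

    protospacer: str
    per_target_sites: dict[str, tuple[CandidateSite, ...]]
    specificity_class: str
    assessments: tuple[AlleleAssessment, ...]

    @property
    def pams(self) -> tuple[str, ...]:
        """Distinct target-allele PAMs of this guide, sorted."""
        return tuple(
            sorted({s.pam for sites in self.per_target_sites.values() for s in sites})
        )


def shared_candidates(
    per_allele: dict[str, list[CandidateSite]],
) -> dict[str, dict[str, list[CandidateSite]]]:
    """Protospacers present in every target allele's candidate list.

    Identity is the 20-mer protospacer sequence regardless of strand or
    position (the guide RNA is the same reagent wherever it binds). Each
    retained protospacer keeps all of its sites per allele. Order follows
    the first allele's enumeration order.
    """
    if not per_allele:
        return {}
    by_allele: dict[str, dict[str, list[CandidateSite]]] = {}
    for name, sites in per_allele.items():
        groups: dict[str, list[CandidateSite]] = {}
        for site in sites:
            groups.setdefault(site.protospacer, []).append(site)
        by_allele[name] = groups
    names = list(per_allele)
    shared: dict[str, dict[str, list[CandidateSite]]] = {}
    for proto in by_allele[names[0]]:
        if all(proto in by_allele[n] for n in names):
            shared[proto] = {n: by_allele[n][proto] for n in names}
    return shared


@dataclass
class DesignResult:
    """Reports plus the resolved genotype context they were computed in."""

    reports: list[GuideReport]
    targets: list[Allele]
    non_targets: list[Allele]
    autocompleted: dict[str, str] = field(default_factory=dict)


def design(
    request: GenotypeRequest,
    db: AlleleDB,
    params: Optional[ScoringParams] = None,
    slack: int = 3,
) -> DesignResult:
    """Run the full design pipeline for one genotype request.

    Homozygous entries are de-duplicated after resolution; a duplicated
    target contributes no off-target constraint against itself. A shared
    guide must satisfy the exon cut-site rule in every target allele.
    Reports are sorted PAM-based first, then by protospacer.
    """
    params = params or ScoringParams()

    resolved: dict[str, Allele] = {}
    autocompleted: dict[str, str] = {}
    target_names: set[str] = set()
    for entered in request.alleles:
        res = resolve(entered, db)
        if res.autocompleted:
            autocompleted[entered] = res.allele.full_name
            logger.warning(
                "autocompleted %s to %s (first full match; confirm the choice)",
                entered,
                res.allele.full_name,
            )
        resolved.setdefault(res.allele.full_name, res.allele)
        if entered in request.targets:
            target_names.add(res.allele.full_name)

    targets = [a for a in resolved.values() if a.full_name in target_names]
    non_targets = [a for a in resolved.values() if a.full_name not in target_names]

    per_allele: dict[str, list[CandidateSite]] = {}
    for i, tgt in enumerate(targets):
        exons = map_exons(tgt.genomic, tgt.coding)
        targets[i] = tgt = with_exons(tgt, exons)
        sites = enumerate_sites(tgt.genomic)
        per_allele[tgt.full_name] = [
            s for s in sites if cut_in_coding(s, exons, slack)
        ]

    reports: list[GuideReport] = []
    for proto, sites_by_allele in shared_candidates(per_allele).items():
        assessments = tuple(
            assess_allele(proto, nt, params) for nt in non_targets
        )
        cls = classify_guide(assessments)
        if cls == REJECTED:
            continue
        reports.append(
            GuideReport(
                protospacer=proto,
                per_target_sites={
                    name: tuple(sites) for name, sites in sites_by_allele.items()
                },
                specificity_class=cls,
                assessments=assessments,
            )
        )
    reports.sort(
        key=lambda r: (0 if r.specificity_class == PAM_BASED else 1, r.protospacer)
    )
    return DesignResult(
        reports=reports,
        targets=targets,
        non_targets=non_targets,
        autocompleted=autocompleted,
    )


def _site_token(allele_name: str, site: CandidateSite) -> str:
    return f"{allele_name}:{site.strand}:{site.window_start}:{site.cut}"


def write_tsv(result: DesignResult, path: Union[str, Path]) -> None:
    """Write the report table (fixed column order and header names)."""
    lines = ["\t".join(TSV_COLUMNS)]
    for r in result.reports:
        target_sites = ";".join(
            _site_token(name, s)
            for name, sites in r.per_target_sites.items()
            for s in sites
        )
        offtargets = ";".join(
            f"{a.allele_name}={a.reason}:"
            f"{min((s.divergence for s in a.sites), default=0.0):.3f}"
            for a in r.assessments
        )
        lines.append(
            "\t".join(
                (
                    r.protospacer,
                    ",".join(r.pams),
                    r.specificity_class,
                    target_sites,
                    offtargets,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def result_to_dict(result: DesignResult) -> dict:
    """JSON-serialisable mirror of the full report structure."""
    return {
        "targets": [a.full_name for a in result.targets],
        "non_targets": [a.full_name for a in result.non_targets],
        "autocompleted": result.autocompleted,
        "guides": [
            {
                "protospacer": r.protospacer,
                "pams": list(r.pams),
                "class": r.specificity_class,
                "per_target_sites": {
                    name: [
                        {
                            "strand": s.strand,
                            "window_start": s.window_start,
                            "cut": s.cut,
                            "pam": s.pam,
                        }
                        for s in sites
                    ]
                    for name, sites in r.per_target_sites.items()
                },
                "assessments": [
                    {
                        "allele": a.allele_name,
                        "reason": a.reason,
                        "sites": [
                            {
                                "strand": s.strand,
                                "offset": s.offset,
                                "pam": s.pam,
                                "mismatch_positions": sorted(s.mismatch_positions),
                                "divergence": s.divergence,
                            }
                            for s in a.sites
                        ],
                    }
                    for a in r.assessments
                ],
            }
            for r in result.reports
        ],
    }


def write_json(result: DesignResult, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2) + "\n")


__all__ = [
    "GenotypeRequest",
    "GuideReport",
    "DesignResult",
    "RequestError",
    "design",
    "shared_candidates",
    "write_tsv",
    "write_json",
    "result_to_dict",
    "PAM_BASED",
    "MISMATCH_BASED",
    "REJECTED",
    "ScoringParams",
]
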