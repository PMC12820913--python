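"""End-to-end design runs on ground-truthed synthetic families."""

import json

import pytest
from click.testing import CliRunner

from hlako.cli import main
from hlako.design_engine import (
    GenotypeRequest,
    RequestError,
    design,
    result_to_dict,
    shared_candidates,
    write_json,
    write_tsv,
)
from hlako.fixtures import FamilyConfig, generate_family
from hlako.guide_design import enumerate_sites, revcomp
from hlako.hla_db import MissingAlleleError
from hlako.offtarget import PAM_BASED, ScoringParams


class TestSharedCandidates:
    def site_list(self, seq):
        return enumerate_sites(seq)

    def test_disjoint_candidate_sets_intersect_to_nothing(self):
        per = {
            "A*90:01": self.site_list("GACGCCGAGGATGGCCGTCACGGTT"),
            "A*91:01": self.site_list("CCATTTTTTTTTTTTTTTTTTTTTTT"),
        }
        assert shared_candidates(per) == {}

    def test_single_allele_is_identity(self):
        sites = self.site_list("GACGCCGAGGATGGCCGTCACGGTT")
        shared = shared_candidates({"A*90:01": sites})
        assert list(shared) == ["GACGCCGAGGATGGCCGTCA"]
        assert shared["GACGCCGAGGATGGCCGTCA"]["A*90:01"] == sites

    def test_planted_shared_protospacer_is_the_sole_intersection(self):
        unit = "GACGCCGAGGATGGCCGTCACGG"
        per = {
            "A*90:01": self.site_list("TAT" + unit + "TATTATTAT"),
            "A*91:01": self.site_list("ATATATA" + unit + "AT"),
        }
        shared = shared_candidates(per)
        assert list(shared) == ["GACGCCGAGGATGGCCGTCA"]


class TestRequestValidation:
    def test_more_than_six_alleles_rejected(self):
        with pytest.raises(RequestError):
            GenotypeRequest(alleles=tuple(f"A*0{i}:01" for i in range(7)),
                            targets=("A*01:01",))

    def test_empty_target_set_rejected(self):
        with pytest.raises(RequestError):
            GenotypeRequest(alleles=("A*01:01",), targets=())

    def test_target_outside_genotype_rejected(self):
        with pytest.raises(RequestError):
            GenotypeRequest(alleles=("A*01:01",), targets=("B*07:02",))


class TestDesign:
    def test_pam_break_family_yields_pam_based_guide_over_the_snp(
        self, pam_family, pam_family_db
    ):
        truth = pam_family.manifest.expected_guides[0]
        result = design(
            GenotypeRequest(
                alleles=(truth.target, truth.non_target), targets=(truth.target,)
            ),
            pam_family_db,
        )
        classes = {r.protospacer: r.specificity_class for r in result.reports}
        assert classes.get(truth.protospacer) == PAM_BASED

    def test_guides_elsewhere_are_rejected_when_alleles_are_otherwise_identical(
        self, pam_family, pam_family_db
    ):
        truth = pam_family.manifest.expected_guides[0]
        result = design(
            GenotypeRequest(
                alleles=(truth.target, truth.non_target), targets=(truth.target,)
            ),
            pam_family_db,
        )
        snp_offsets = {v.offset for v in pam_family.manifest.variants}
        for report in result.reports:
            # every surviving guide must overlap a planted difference
            sites = report.per_target_sites[truth.target]
            assert any(
                s.window_start <= off < s.window_start + 23
                for s in sites
                for off in snp_offsets
            )

    def test_reported_protospacers_refound_with_ngg_in_every_target(
        self, pam_family, pam_family_db
    ):
        truth = pam_family.manifest.expected_guides[0]
        result = design(
            GenotypeRequest(
                alleles=(truth.target, truth.non_target), targets=(truth.target,)
            ),
            pam_family_db,
        )
        assert result.reports
        for report in result.reports:
            for tgt in result.targets:
                genomic = tgt.genomic
                hits = [
                    s for s in enumerate_sites(genomic)
                    if s.protospacer == report.protospacer
                ]
                assert hits, (report.protospacer, tgt.full_name)

    def test_all_alleles_as_targets_is_vacuously_pam_based(self, pam_family_db):
        names = tuple(a.full_name for a in pam_family_db.alleles)
        result = design(GenotypeRequest(alleles=names, targets=names), pam_family_db)
        assert result.reports
        assert all(r.specificity_class == PAM_BASED for r in result.reports)

    def test_homozygous_genotype_deduplicated(self, pam_family_db):
        name = pam_family_db.alleles[0].full_name
        result = design(
            GenotypeRequest(alleles=(name, name), targets=(name,)), pam_family_db
        )
        assert result.non_targets == []  # the duplicate is no off-target constraint
        assert result.reports

    def test_adding_a_non_target_never_adds_guides(self):
        family = generate_family(FamilyConfig(seed=3, n_alleles=3, n_pam_snps=2))
        db = family.load_db()
        names = family.manifest.allele_names
        small = design(
            GenotypeRequest(alleles=(names[0], names[1]), targets=(names[0],)), db
        )
        large = design(
            GenotypeRequest(alleles=tuple(names), targets=(names[0],)), db
        )
        assert {r.protospacer for r in large.reports} <= {
            r.protospacer for r in small.reports
        }

    def test_multi_target_intersection_only_shrinks_candidates(self):
        family = generate_family(FamilyConfig(seed=5, n_alleles=3, n_pam_snps=1))
        db = family.load_db()
        names = family.manifest.allele_names
        single = design(
            GenotypeRequest(alleles=(names[0], names[2]), targets=(names[0],)), db
        )
        both = design(
            GenotypeRequest(
                alleles=(names[0], names[1], names[2]), targets=(names[0], names[1])
            ),
            db,
        )
        assert {r.protospacer for r in both.reports} <= {
            r.protospacer for r in single.reports
        }

    def test_rerun_is_bit_identical(self, pam_family, pam_family_db):
        names = tuple(pam_family.manifest.allele_names)
        req = GenotypeRequest(alleles=names, targets=(names[0],))
        a = result_to_dict(design(req, pam_family_db))
        b = result_to_dict(design(req, pam_family_db))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_missing_allele_propagates_with_name(self, pam_family_db):
        with pytest.raises(MissingAlleleError, match="B\\*99:99"):
            design(
                GenotypeRequest(alleles=("B*99:99",), targets=("B*99:99",)),
                pam_family_db,
            )

    def test_reports_sorted_pam_based_first_then_lexicographic(self):
        family = generate_family(
            FamilyConfig(
                seed=9, n_alleles=3, n_pam_snps=1, protospacer_positions=(18, 19, 20)
            )
        )
        db = family.load_db()
        names = family.manifest.allele_names
        result = design(GenotypeRequest(alleles=tuple(names), targets=(names[0],)), db)
        keys = [
            (0 if r.specificity_class == PAM_BASED else 1, r.protospacer)
            for r in result.reports
        ]
        assert keys == sorted(keys)


class TestOutputsAndCli:
    def _family_on_disk(self, tmp_path):
        family = generate_family(FamilyConfig(seed=11, n_pam_snps=1))
        paths = family.write(tmp_path)
        return family, paths

    def test_tsv_and_json_mirror_report_structure(self, tmp_path, pam_family, pam_family_db):
        names = tuple(pam_family.manifest.allele_names)
        result = design(
            GenotypeRequest(alleles=names, targets=(names[0],)), pam_family_db
        )
        tsv = tmp_path / "guides.tsv"
        js = tmp_path / "guides.json"
        write_tsv(result, tsv)
        write_json(result, js)
        lines = tsv.read_text().splitlines()
        assert lines[0] == "protospacer\tpams\tclass\ttarget_sites\tofftargets"
        assert len(lines) == 1 + len(result.reports)
        payload = json.loads(js.read_text())
        assert [g["protospacer"] for g in payload["guides"]] == [
            r.protospacer for r in result.reports
        ]

    def test_cli_design_exit_codes(self, tmp_path):
        family, paths = self._family_on_disk(tmp_path)
        names = family.manifest.allele_names
        runner = CliRunner()
        ok = runner.invoke(
            main,
            ["design", "--db-gen", str(paths["gen"]), "--db-nuc", str(paths["nuc"]),
             "--alleles", ",".join(names), "--targets", names[0],
             "--out", str(tmp_path / "g.tsv")],
        )
        assert ok.exit_code == 0, ok.output
        # targeting the PAM-broken allele: every candidate cleaves the backbone
        none = runner.invoke(
            main,
            ["design", "--db-gen", str(paths["gen"]), "--db-nuc", str(paths["nuc"]),
             "--alleles", ",".join(names), "--targets", names[1],
             "--out", str(tmp_path / "g2.tsv")],
        )
        assert none.exit_code == 3, none.output
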