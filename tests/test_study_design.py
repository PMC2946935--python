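"""Study tables, schema uniformity, stratification and contrasts."""

import os

import pytest

from deskpipe import fixtures as fx
from deskpipe.predicates import PredicateError
from deskpipe.study_design import (
    CohortDefinition,
    UniformityError,
    build_from_directory,
    build_from_metadata_files,
    build_from_spreadsheet,
    enumerate_contrasts,
    stratify,
    write_subject_xml,
)


@pytest.fixture
def file_tree(tmp_path):
    """3 matching .txt files (1 nested), one decoy csv, one non-matching."""
    (tmp_path / "sub").mkdir()
    for name in ("s01_scan.txt", "s02_scan.txt"):
        (tmp_path / name).write_text("data\n")
    (tmp_path / "sub" / "s03_scan.txt").write_text("data\n")
    (tmp_path / "decoy.csv").write_text("a,b\n1,2\n")
    (tmp_path / "readme.md").write_text("hi\n")
    return tmp_path


class TestDirectoryBuild:
    def test_recursive_matches_all_three(self, file_tree):
        table, report = build_from_directory(str(file_tree), r"(s\d+)_scan\.txt")
        assert sorted(r.subject_id for r in table.records) == ["s01", "s02", "s03"]

    def test_non_recursive_matches_top_level_only(self, file_tree):
        table, _ = build_from_directory(str(file_tree), r"(s\d+)_scan\.txt",
                                        recursive=False)
        assert sorted(r.subject_id for r in table.records) == ["s01", "s02"]

    def test_type_filter_excludes_decoy(self, tmp_path):
        import numpy as np
        from deskpipe.smartlines import Volume, write_volume

        write_volume(str(tmp_path / "s01.nii"),
                     Volume(np.zeros((4, 4, 4), dtype=np.int16)), "nifti-1", "short")
        (tmp_path / "s02.nii").write_text("a,b\n1,2\n")  # csv decoy in disguise
        table, report = build_from_directory(
            str(tmp_path), r"(s\d+)\.nii", type_filter="nifti-1"
        )
        assert [r.subject_id for r in table.records] == ["s01"]
        assert any("s02" in p for p, _ in report.skipped)

    def test_zero_matches_warns_not_errors(self, tmp_path):
        table, report = build_from_directory(str(tmp_path), r"(nothing)\.xyz")
        assert len(table) == 0 and report.warnings

    def test_unreadable_root_errors(self, tmp_path):
        with pytest.raises(NotADirectoryError):
            build_from_directory(str(tmp_path / "ghost"), r"(x)")


class TestMetadataBuild:
    def _write(self, path, sid, fields):
        write_subject_xml(str(path), sid, fields)

    def test_uniform_files_give_uniform_schema(self, tmp_path):
        for i in (1, 2):
            self._write(tmp_path / f"s{i}.xml", f"s{i}",
                        {"mmse": 20 + i, "image_path": f"/img{i}.nii"})
        table, _ = build_from_metadata_files(str(tmp_path), "image_path")
        assert len(table) == 2
        assert {f for f, _ in table.schema} == {"mmse", "image_path"}

    def test_missing_data_path_element_is_reported_and_excluded(self, tmp_path):
        self._write(tmp_path / "s1.xml", "s1", {"mmse": 20, "image_path": "/a.nii"})
        self._write(tmp_path / "s2.xml", "s2", {"mmse": 21})
        table, report = build_from_metadata_files(str(tmp_path), "image_path")
        assert len(table) == 1
        assert any("s2" in p for p, _ in report.skipped)

    def test_inconsistent_field_sets_raise_uniformity_error(self, tmp_path):
        self._write(tmp_path / "s1.xml", "s1", {"mmse": 20, "image_path": "/a.nii"})
        self._write(tmp_path / "s2.xml", "s2",
                    {"age": 70, "image_path": "/b.nii"})
        with pytest.raises(UniformityError, match="s2.xml"):
            build_from_metadata_files(str(tmp_path), "image_path")


class TestSpreadsheetBuild:
    def _csv(self, tmp_path, rows):
        p = tmp_path / "t.csv"
        p.write_text("\n".join(rows) + "\n")
        return str(p)

    def test_round_trip_through_generated_xml(self, tmp_path):
        img1, img2 = tmp_path / "a.nii", tmp_path / "b.nii"
        csv_path = self._csv(tmp_path, [
            "subject_id,mmse,image_path",
            f"s1,22,{img1}",
            f"s2,28,{img2}",
        ])
        table, _ = build_from_spreadsheet(csv_path, "image_path")
        assert len(table) == 2
        meta_dir = os.path.join(tmp_path, "metadata")
        table2, _ = build_from_metadata_files(meta_dir, "image_path")
        t1 = {r.subject_id: {k: v for k, v in r.metadata.items() if k != "metadata_xml"}
              for r in table.records}
        t2 = {r.subject_id: {k: v for k, v in r.metadata.items()}
              for r in table2.records}
        assert t1 == t2

    def test_empty_data_section_warns(self, tmp_path):
        table, report = build_from_spreadsheet(
            self._csv(tmp_path, ["subject_id,image_path"]), "image_path"
        )
        assert len(table) == 0 and report.warnings

    def test_ragged_row_names_row_number(self, tmp_path):
        csv_path = self._csv(tmp_path, [
            "subject_id,mmse,image_path",
            "s1,22,/a.nii",
            "s2,28",
        ])
        with pytest.raises(ValueError, match="row 3"):
            build_from_spreadsheet(csv_path, "image_path")

    def test_missing_path_column_errors(self, tmp_path):
        with pytest.raises(ValueError, match="path"):
            build_from_spreadsheet(self._csv(tmp_path, ["a,b", "1,2"]), "image_path")


class TestStratify:
    @pytest.fixture
    def adni_table(self, tmp_path):
        csv_path = fx.make_study(fx.FixtureConfig(seed=11),
                                 str(tmp_path / "study"), write_volumes=False)
        table, _ = build_from_spreadsheet(csv_path, "image_path")
        return table

    def test_mmse_cutoffs_reproduce_documented_cohort_sizes(self, adni_table):
        cohorts, report = stratify(adni_table, fx.COHORT_DEFINITIONS)
        sizes = {c.name: len(c) for c in cohorts}
        # brute-force oracle: recount by a raw row scan of the table
        expected = {"AD": 0, "MCI": 0, "NC": 0}
        for rec in adni_table.records:
            m = rec.metadata["mmse"]
            if 10 <= m <= 19:
                expected["AD"] += 1
            elif 20 <= m <= 25:
                expected["MCI"] += 1
            elif 26 <= m <= 30:
                expected["NC"] += 1
        assert sizes == expected == {"AD": 18, "MCI": 49, "NC": 61}
        assert not report.unassigned and not report.multi_assigned

    def test_exhaustive_disjoint_predicates_partition_the_table(self, adni_table):
        cohorts, report = stratify(adni_table, fx.COHORT_DEFINITIONS)
        assert sum(len(c) for c in cohorts) == len(adni_table)

    def test_false_predicate_gives_empty_cohort_all_unassigned(self, adni_table):
        cohorts, report = stratify(adni_table, [CohortDefinition("none", "false")])
        assert len(cohorts[0]) == 0
        assert len(report.unassigned) == len(adni_table)

    def test_overlapping_predicates_reported_as_multi_assigned(self, adni_table):
        cohorts, report = stratify(adni_table, [
            CohortDefinition("low", "mmse <= 25"),
            CohortDefinition("mid", "mmse >= 20"),
        ])
        multi_ids = {sid for sid, _ in report.multi_assigned}
        overlap = {r.subject_id for r in adni_table.records
                   if 20 <= r.metadata["mmse"] <= 25}
        assert multi_ids == overlap
        for sid, names in report.multi_assigned:
            assert set(names) == {"low", "mid"}

    def test_unknown_field_in_predicate_errors(self, adni_table):
        with pytest.raises(PredicateError, match="unknown field"):
            stratify(adni_table, [CohortDefinition("x", "telomere > 5")])

    def test_members_satisfy_their_predicate(self, adni_table):
        cohorts, _ = stratify(adni_table, fx.COHORT_DEFINITIONS)
        for cohort in cohorts:
            lo, hi = fx.MMSE_CUTOFFS[cohort.name]
            assert all(lo <= r.metadata["mmse"] <= hi for r in cohort.members)


class TestContrasts:
    def test_three_cohorts_six_measures_gives_eighteen(self):
        contrasts = enumerate_contrasts(
            ["AD", "MCI", "NC"],
            ["volume", "surface_area", "mean_curvature",
             "shape_index", "curvedness", "fractal_dimension"],
        )
        assert len(contrasts) == 18
        assert {(c.cohort_a, c.cohort_b) for c in contrasts} == {
            ("AD", "MCI"), ("AD", "NC"), ("MCI", "NC")
        }

    def test_two_cohorts_one_measure(self):
        assert len(enumerate_contrasts(["a", "b"], ["m"])) == 1

    def test_four_cohorts_two_measures_matches_brute_force(self):
        contrasts = enumerate_contrasts(list("abcd"), ["m1", "m2"])
        # brute-force: all unordered pairs x measures
        from itertools import combinations

        expected = {(a, b, m) for a, b in combinations("abcd", 2)
                    for m in ("m1", "m2")}
        assert {(c.cohort_a, c.cohort_b, c.measure_id) for c in contrasts} == expected
        assert len(contrasts) == 12

    def test_deterministic_lexicographic_order(self):
        c1 = enumerate_contrasts(["b", "a", "c"], ["y", "x"])
        c2 = enumerate_contrasts(["c", "b", "a"], ["x", "y"])
        assert c1 == c2

    def test_fewer_than_two_cohorts_errors(self):
        with pytest.raises(ValueError):
            enumerate_contrasts(["only"], ["m"])
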