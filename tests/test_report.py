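"""Summary assembly, manual-check flag truth table, statistics, output files."""

import json

import pytest

from mispscreen.ingest import ModificationProfile, PeptideRecord, parse_modifications
from mispscreen.lca_backend import LcaResult, load_offline_table, parse_lineage
from mispscreen.permute import enumerate_misps
from mispscreen.report import (
    build_summary,
    count_deamidatable_sites,
    dataset_statistics,
    needs_manual_check,
    summary_to_json_obj,
    write_outputs,
)
from mispscreen.taxonomy import PeptideCategory


def _lca(peptide, taxon_id, depth_tag="genus"):
    lineage = parse_lineage(f"superkingdom:2759:Eukaryota|{depth_tag}:{taxon_id}:T{taxon_id}")
    return LcaResult(peptide, taxon_id, f"T{taxon_id}", depth_tag, lineage)


TWO_DISTINCT = [_lca("X", 10), _lca("Y", 11)]
ONE_LCA = [_lca("X", 10)]
TWO_SAME = [_lca("X", 10), _lca("Y", 10)]


class TestManualCheckFlag:
    """The flag is the conjunction: d < deamidatable sites, d != 0,
    and >= 2 distinct MISP LCAs.  All combinations of the three conjuncts."""

    @pytest.mark.parametrize(
        "sequence, d, lcas, expected",
        [
            # A = d < sites, B = d != 0, C = >= 2 distinct LCAs
            ("NQNK", 1, TWO_DISTINCT, True),  # A B C
            ("NQNK", 1, TWO_SAME, False),  # A B ¬C
            ("NQNK", 0, TWO_DISTINCT, False),  # A ¬B C
            ("NQNK", 0, ONE_LCA, False),  # A ¬B ¬C
            ("NQNK", 3, TWO_DISTINCT, False),  # ¬A B C
            ("NQNK", 3, TWO_SAME, False),  # ¬A B ¬C
            ("DEGK", 0, TWO_DISTINCT, False),  # ¬A ¬B C (no N/Q sites)
            ("DEGK", 0, [], False),  # ¬A ¬B ¬C
            # d exceeding the site count also fails the first conjunct
            ("NNGKTEYGLFQINNK", 3, TWO_DISTINCT, True),  # 5 sites, d=3
            ("NGK", 1, TWO_DISTINCT, False),  # 1 site, d=1
        ],
    )
    def test_truth_table(self, sequence, d, lcas, expected):
        record = PeptideRecord(sequence, "", 0)
        assert needs_manual_check(record, ModificationProfile(d), lcas) is expected

    def test_nterminal_q_excluded_when_pyroglu(self):
        # QNGK has two N/Q residues, but pyroGlu claims the N-terminal Q:
        # with d=1 == 1 remaining site, the first conjunct fails
        profile = ModificationProfile(1, pyroglu_from_q=True)
        assert count_deamidatable_sites("QNGK", profile) == 1
        record = PeptideRecord("QNGK", "", 0)
        assert needs_manual_check(record, profile, TWO_DISTINCT) is False
        # without pyroGlu the same peptide is flagged
        assert needs_manual_check(record, ModificationProfile(1), TWO_DISTINCT) is True


class TestBuildSummary:
    def test_dairy_ambiguity_categorised_different(self, worked_paths):
        _, table_path = worked_paths
        table = load_offline_table(table_path)
        record = PeptideRecord("TPEVDDEALEK", "", 0)
        profile = ModificationProfile(0)
        perm_set = enumerate_misps(record.sequence, profile)
        lca_map = {seq: table.get(seq) for seq in {record.sequence, *perm_set.sequences}}
        summary = build_summary(record, profile, perm_set, lca_map)
        assert summary.total_misps == 32
        assert [seq for seq, _ in summary.misps_with_lca] == ["TPEVDNEALEK"]
        assert summary.category is PeptideCategory.DIFFERENT
        assert not summary.all_lcas_identical
        assert not summary.manual_check_required

    def test_pyroglu_ambiguity_categorised_less_specific(self, worked_paths):
        _, table_path = worked_paths
        table = load_offline_table(table_path)
        record = PeptideRecord("QEVGGEALGR", "Gln->pyro-Glu (N-term Q)", 1)
        profile = parse_modifications(record.raw_modifications)
        perm_set = enumerate_misps(record.sequence, profile)
        lca_map = {seq: table.get(seq) for seq in {record.sequence, *perm_set.sequences}}
        summary = build_summary(record, profile, perm_set, lca_map)
        assert summary.category is PeptideCategory.LESS_SPECIFIC

    def test_empty_permutation_set(self):
        record = PeptideRecord("GGGK", "", 0)
        profile = ModificationProfile(0)
        perm_set = enumerate_misps(record.sequence, profile)
        summary = build_summary(record, profile, perm_set, {"GGGK": None})
        assert summary.total_misps == 0
        assert summary.category is PeptideCategory.NO_ALTERNATE

    def test_identical_misp_lca_sets_all_identical(self):
        record = PeptideRecord("NGGGK", "Deamidated (NQ)", 0)
        profile = ModificationProfile(1)
        perm_set = enumerate_misps(record.sequence, profile)  # NGGGK, DGGGK
        lca_map = {"NGGGK": _lca("NGGGK", 10), "DGGGK": _lca("DGGGK", 10)}
        summary = build_summary(record, profile, perm_set, lca_map)
        assert summary.all_lcas_identical
        assert summary.category is PeptideCategory.ALL_IDENTICAL

    def test_unresolved_lookup_noted_not_dropped(self):
        record = PeptideRecord("NGGGK", "Deamidated (NQ)", 0)
        profile = ModificationProfile(1)
        perm_set = enumerate_misps(record.sequence, profile)
        lca_map = {"NGGGK": _lca("NGGGK", 10), "DGGGK": None}
        summary = build_summary(
            record, profile, perm_set, lca_map, unresolved={"DGGGK": "5 retries failed"}
        )
        assert summary.misps_with_lca == ()
        assert any("DGGGK" in note for note in summary.notes)

    def test_uncovered_misp_is_an_error(self):
        record = PeptideRecord("NGGGK", "", 0)
        profile = ModificationProfile(1)
        perm_set = enumerate_misps(record.sequence, profile)
        with pytest.raises(KeyError):
            build_summary(record, profile, perm_set, {"NGGGK": None})


def _summary_with_misps(n, category=PeptideCategory.NO_ALTERNATE):
    from mispscreen.report import SummaryRecord

    return SummaryRecord(
        input_sequence="PEPTIDEK",
        raw_modifications="",
        input_lca=None,
        total_misps=n,
        misps_with_lca=(),
        all_lcas_identical=True,
        manual_check_required=False,
        category=category,
    )


class TestDatasetStatistics:
    def test_median_lower_middle_and_mode_smallest_tie(self):
        stats = dataset_statistics([_summary_with_misps(c) for c in [0, 2, 4]])
        assert stats.median_misps == 2
        assert stats.mode_misps == 0  # all counts tie; smallest wins

    def test_even_n_and_zero_partition(self):
        stats = dataset_statistics([_summary_with_misps(c) for c in [2, 2, 4, 0]])
        assert stats.n_without_misps == 1
        assert stats.n_with_misps == 3
        assert stats.mode_misps == 2
        assert stats.median_misps == 2  # lower middle of [0,2,2,4]

    def test_mean_truncated_not_rounded(self):
        stats = dataset_statistics([_summary_with_misps(c) for c in [1, 2, 2]])
        assert stats.mean_misps == 1.6  # 5/3 = 1.666... truncates

    def test_empty_input(self):
        stats = dataset_statistics([])
        assert stats.n_peptides == 0 and stats.total_misps_sum == 0

    def test_alternate_lca_count(self):
        summaries = [
            _summary_with_misps(2, PeptideCategory.DIFFERENT),
            _summary_with_misps(2, PeptideCategory.ALL_IDENTICAL),
            _summary_with_misps(2, PeptideCategory.LESS_SPECIFIC),
        ]
        assert dataset_statistics(summaries).n_with_alternate_lca == 2


class TestWriteOutputs:
    def _run(self, out_dir):
        record = PeptideRecord("NGGGK", "Deamidated (NQ)", 0)
        profile = ModificationProfile(1)
        perm_set = enumerate_misps(record.sequence, profile)
        lca_map = {"NGGGK": _lca("NGGGK", 10), "DGGGK": _lca("DGGGK", 11)}
        summary = build_summary(record, profile, perm_set, lca_map)
        obj = summary_to_json_obj(summary, profile, perm_set, lca_map)
        return write_outputs([summary], [obj], out_dir, "run")

    def test_three_artifacts_written(self, tmp_path):
        results, permutations, json_path = self._run(tmp_path)
        assert results.name == "run_results.csv"
        perm_lines = permutations.read_text().splitlines()
        assert len(perm_lines) == 3  # header + identity row + one MISP
        payload = json.loads(json_path.read_text())
        assert payload["schema_version"] == 1

    def test_identity_row_flagged_without_lca(self, tmp_path):
        _, permutations, _ = self._run(tmp_path)
        rows = permutations.read_text().splitlines()[1:]
        identity = [r for r in rows if ",True," in r]
        assert len(identity) == 1
        assert identity[0].endswith(",")  # LCA cell empty for identity

    def test_byte_identical_across_runs(self, tmp_path):
        dir_a = tmp_path / "a"
        dir_b = tmp_path / "b"
        dir_a.mkdir()
        dir_b.mkdir()
        paths_a = self._run(dir_a)
        paths_b = self._run(dir_b)
        for pa, pb in zip(paths_a, paths_b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_json_projects_onto_csv(self, tmp_path):
        results, _, json_path = self._run(tmp_path)
        payload = json.loads(json_path.read_text())
        csv_rows = results.read_text().splitlines()
        assert len(csv_rows) - 1 == len(payload["peptides"])
        for obj, row in zip(payload["peptides"], csv_rows[1:]):
            assert row.startswith(obj["input_sequence"] + ",")
            assert f",{obj['total_misps']}," in row
            assert obj["category"] in row

    def test_empty_summary_list(self, tmp_path):
        results, permutations, json_path = write_outputs([], [], tmp_path, "empty")
        assert len(results.read_text().splitlines()) == 1  # header only
        assert len(permutations.read_text().splitlines()) == 1
        assert json.loads(json_path.read_text())["peptides"] == []

    def test_missing_directory_aborts(self, tmp_path):
        with pytest.raises(NotADirectoryError):
            self._run(tmp_path / "nope")
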