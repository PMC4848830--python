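from pathlib import Path

import pytest
from click.testing import CliRunner

from imirp import (
    InvalidSitePolicy,
    MutationStrategy,
    ProjectConfig,
    assemble,
    diff_predictions,
    is_valid,
    predict_sites,
    read_sequence,
    run_project,
    write_reports,
)
from imirp.assembly import parse_sites_csv
from imirp.cli import main as cli_main
from imirp.errors import UsageError
from imirp.fixtures import make_project_fixture


@pytest.fixture(scope="module")
def solved_project():
    fx = make_project_fixture(n_sites=3, spacing=9, trap=False, rng_seed=13)
    config = ProjectConfig(
        sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
        species=fx.species_code, anchors=fx.anchors, rng_seed=2,
    )
    return fx, run_project(config)


class TestAssemble:
    def test_output_matches_chosen_mutants_inside_spans_only(self, solved_project):
        fx, result = solved_project
        assembled = result.assembled_sequence
        assert len(assembled) == len(fx.sequence)
        changed = {
            p
            for r in result.region_results
            for p in r.valid_mutants[result.selections[r.region_id] - 1]
            .candidate.changed_positions
        }
        for i, (a, b) in enumerate(zip(fx.sequence, assembled), start=1):
            assert (a != b) == (i in changed)

    def test_single_region_selection_equals_candidate_sequence(self):
        fx = make_project_fixture(n_sites=1, spacing=0, trap=False, rng_seed=3)
        result = run_project(ProjectConfig(
            sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
            species=fx.species_code, anchors=fx.anchors, rng_seed=1,
        ))
        chosen = result.region_results[0].valid_mutants[0].candidate
        assert result.assembled_sequence == chosen.full_sequence

    def test_missing_selection_is_usage_error(self, solved_project):
        fx, result = solved_project
        with pytest.raises(UsageError, match="unsolved or unselected"):
            assemble(result.input_sequence, result.region_results, {})

    def test_global_reverification_of_assembled_sequence(self, solved_project):
        fx, result = solved_project
        fresh = predict_sites(result.assembled_sequence, result.mirnas,
                              fx.gu_allowed)
        new = diff_predictions(result.input_sites, fresh)
        assert is_valid(new, result.config.policy)
        assert set(new) == set(result.new_sites)

    def test_explicit_index_selection(self):
        fx = make_project_fixture(n_sites=1, spacing=0, trap=False, rng_seed=3)
        base = dict(sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
                    species=fx.species_code, anchors=fx.anchors, rng_seed=1)
        first = run_project(ProjectConfig(**base, selection=[1]))
        second = run_project(ProjectConfig(**base, selection=[2]))
        assert first.assembled_sequence != second.assembled_sequence


class TestReports:
    def test_report_files_written_and_deterministic(self, solved_project, tmp_path):
        fx, result = solved_project
        a, b = tmp_path / "a", tmp_path / "b"
        files = write_reports(result, a)
        write_reports(result, b)
        for f in files:
            assert f.exists()
            assert f.read_bytes() == (b / f.name).read_bytes()

    def test_csv_round_trip_reproduces_predictions(self, solved_project, tmp_path):
        fx, result = solved_project
        write_reports(result, tmp_path)
        assert parse_sites_csv(tmp_path / "input_predictions.csv") == \
            result.input_sites

    def test_new_sites_row_count_matches_diff(self, solved_project, tmp_path):
        fx, result = solved_project
        write_reports(result, tmp_path)
        rows = (tmp_path / "new_sites.csv").read_text().strip().splitlines()
        assert len(rows) - 1 == len(result.new_sites)

    def test_project_info_records_rerun_metadata(self, solved_project, tmp_path):
        fx, result = solved_project
        write_reports(result, tmp_path)
        info = (tmp_path / "project_info.txt").read_text()
        for needed in (fx.sequence, result.assembled_sequence,
                       f"rng seed: {result.config.rng_seed}",
                       f"species: {fx.species_code}", "mature.fa"):
            assert needed in info


class TestRunProject:
    def test_empty_anchor_list_is_usage_error(self, solved_project):
        fx, _ = solved_project
        with pytest.raises(UsageError, match="at least one"):
            run_project(ProjectConfig(
                sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
                species=fx.species_code, anchors=[],
            ))

    def test_anchor_out_of_range_is_usage_error(self, solved_project):
        fx, _ = solved_project
        with pytest.raises(UsageError, match="outside the sequence"):
            run_project(ProjectConfig(
                sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
                species=fx.species_code, anchors=[len(fx.sequence)],
            ))

    def test_unknown_species_proceeds_with_warning(self, solved_project, caplog):
        fx, _ = solved_project
        with caplog.at_level("WARNING"):
            result = run_project(ProjectConfig(
                sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
                species="xyz", anchors=fx.anchors,
            ))
        assert "xyz" in caplog.text
        assert result.all_solved  # nothing to create sites for

    def test_byte_reproducible_given_seed(self, solved_project, tmp_path):
        fx, _ = solved_project
        outs = []
        for name in ("r1", "r2"):
            result = run_project(ProjectConfig(
                sequence=fx.sequence, mirna_fasta=fx.mirna_fasta,
                species=fx.species_code, anchors=fx.anchors, rng_seed=2,
            ))
            write_reports(result, tmp_path / name)
            outs.append({
                f.name: f.read_bytes() for f in sorted((tmp_path / name).iterdir())
            })
        assert outs[0] == outs[1]


class TestReadSequence:
    def test_raw_string_whitespace_stripped(self):
        assert read_sequence("ACGT\nACGT ") == "ACGTACGT"

    def test_fasta_file(self, tmp_path):
        p = tmp_path / "utr.fa"
        p.write_text(">utr test\nACGTAC\nGTAC\n")
        assert read_sequence(str(p)) == "ACGTACGTAC"

    def test_plain_text_file(self, tmp_path):
        p = tmp_path / "utr.txt"
        p.write_text("ACGT\nACGT\n")
        assert read_sequence(str(p)) == "ACGTACGT"


class TestCli:
    @pytest.fixture()
    def project_files(self, tmp_path):
        fx = make_project_fixture(n_sites=2, spacing=9, trap=False, rng_seed=23)
        fasta = tmp_path / "mature.fa"
        fasta.write_text(fx.mirna_fasta)
        seq = tmp_path / "utr.fa"
        seq.write_text(f">utr\n{fx.sequence}\n")
        return fx, fasta, seq

    def test_run_end_to_end(self, project_files, tmp_path):
        fx, fasta, seq = project_files
        out = tmp_path / "out"
        args = ["run", "--sequence", str(seq), "--mirna-fasta", str(fasta),
                "--species", fx.species_code, "--seed", "1", "--out", str(out)]
        for a in fx.anchors:
            args += ["--site", str(a)]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        assert (out / "project_info.txt").exists()
        assert "region 1" in result.output and "region 2" in result.output
        assert "assembled mutant written" in result.output

    def test_run_infeasible_strategy_exits_nonzero_naming_regions(
        self, project_files, tmp_path
    ):
        fx, fasta, seq = project_files
        poly_a = tmp_path / "polyA.txt"
        poly_a.write_text("A" * 40)
        result = CliRunner().invoke(cli_main, [
            "run", "--sequence", str(poly_a), "--mirna-fasta", str(fasta),
            "--species", fx.species_code, "--site", "10", "--bases", "A",
            "--out", str(tmp_path / "o"),
        ])
        assert result.exit_code == 2
        assert "region(s) 1" in result.output
        assert "different mutation strategy" in result.output

    def test_run_without_sites_fails(self, project_files, tmp_path):
        fx, fasta, seq = project_files
        result = CliRunner().invoke(cli_main, [
            "run", "--sequence", str(seq), "--mirna-fasta", str(fasta),
            "--species", fx.species_code, "--out", str(tmp_path / "o"),
        ])
        assert result.exit_code != 0

    def test_predict_prints_planted_sites(self, project_files):
        fx, fasta, seq = project_files
        result = CliRunner().invoke(cli_main, [
            "predict", "--sequence", str(seq), "--mirna-fasta", str(fasta),
            "--species", fx.species_code,
        ])
        assert result.exit_code == 0
        for s in fx.planted_sites:
            assert (
                f"{s.mirna_id},SYN" in result.output or s.mirna_id in result.output
            )
            assert f",{s.site_type.value},{s.window_start}," in result.output

    def test_count_reports_region_spaces(self, project_files):
        fx, fasta, seq = project_files
        args = ["count", "--sequence", str(seq)]
        for a in fx.anchors:
            args += ["--site", str(a)]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0
        assert result.output.count("45 candidate mutant(s)") == 2
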