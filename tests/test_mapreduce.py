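import subprocess
import sys
import time
from pathlib import Path

import pytest

from rsdlite.evodist import build_rate_model
from rsdlite.mapreduce_lite import (
    ExecutionContext,
    ExecutorAbortError,
    ExecutorConfig,
    IncompleteStoreError,
    ResultStore,
    RunnerFile,
    generate_runner_file,
    missing_hit_tables,
    parse_command,
    run_blast_phase,
    run_mapper,
    run_ortholog_phase,
    run_two_phase,
)
from rsdlite.rsdcore import ParamSetting, param_grid
from rsdlite.seqio import format_genome, save_genome
from rsdlite.simgen import SimConfig, simulate_genome_pair

FAST = ExecutorConfig(n_workers=2, task_timeout=30.0)


@pytest.fixture()
def ctx(tmp_path):
    return ExecutionContext(
        genomes_root=tmp_path / "genomes",
        store_root=tmp_path / "store",
        parts_dir=tmp_path / "parts",
    )


@pytest.fixture()
def store(tmp_path):
    return ResultStore(tmp_path / "store")


def runner_of(tmp_path, *lines):
    return RunnerFile.write(lines, "test", tmp_path / "runner")


class TestCommandGrammar:
    def test_blast_line_round_trips(self):
        name, args = parse_command(
            "rsd-blast --query-genome A.aa --db-genome B.aa --evalue 1e-05"
        )
        assert name == "rsd-blast"
        assert args == {"query_genome": "A.aa", "db_genome": "B.aa", "evalue": 1e-5}

    def test_ortho_line_round_trips(self):
        name, args = parse_command(
            "rsd-ortho --genome-a A.aa --genome-b B.aa --divergence 0.8 --evalue 1e-10"
        )
        assert name == "rsd-ortho"
        assert args["divergence"] == 0.8

    @pytest.mark.parametrize(
        "line",
        [
            "",
            "frobnicate --x 1",
            "rsd-blast --query-genome A.aa",
            "rsd-blast --query-genome A.aa --db-genome B.aa --evalue not-a-number",
            "rsd-ortho --genome-a A.aa --genome-b B.aa --divergence 0.8 --evalue 1e-10 --bogus 1",
        ],
    )
    def test_bad_lines_rejected(self, line):
        with pytest.raises(ValueError):
            parse_command(line)


class TestGenerateRunnerFile:
    def test_cloud_scale_ortholog_task_count(self, tmp_path):
        names = [f"N{i:02d}" for i in range(55)]
        existing = [f"O{i:03d}" for i in range(399)]
        settings = param_grid((0.2, 0.5, 0.8), (1e-20, 1e-15, 1e-10, 1e-5))
        runner = generate_runner_file(
            names, existing, "ortholog", settings, tmp_path / "ortho_runner"
        )
        assert len(runner) == 281_160

    def test_cloud_scale_blast_task_count(self, tmp_path):
        names = [f"N{i:02d}" for i in range(55)]
        existing = [f"O{i:03d}" for i in range(399)]
        runner = generate_runner_file(
            names, existing, "blast", [ParamSetting(0.5, 1e-5)], tmp_path / "blast_runner"
        )
        assert len(runner) == 46_860

    def test_empty_input_gives_empty_runner(self, tmp_path):
        runner = generate_runner_file(
            [], [], "blast", [ParamSetting(0.5, 1e-5)], tmp_path / "r"
        )
        assert len(runner) == 0

    def test_overlapping_names_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="both new and existing"):
            generate_runner_file(["A"], ["A"], "blast", [], tmp_path / "r")

    def test_line_order_is_deterministic(self, tmp_path):
        settings = param_grid((0.5,), (1e-5, 1e-10))
        r1 = generate_runner_file(["B", "A"], ["C"], "ortholog", settings, tmp_path / "r1")
        r2 = generate_runner_file(["A", "B"], ["C"], "ortholog", settings, tmp_path / "r2")
        assert r1.lines == r2.lines


class TestRunMapper:
    def test_part_files_equal_successful_tasks(self, tmp_path, store, ctx):
        runner = runner_of(tmp_path, *[f"rsd-echo --text t{i}" for i in range(5)])
        reports = run_mapper(runner, FAST, store, ctx)
        assert [r.status for r in reports] == ["ok"] * 5
        parts = sorted(p.name for p in ctx.parts_dir.glob("part-*"))
        assert parts == [f"part-{i:05d}" for i in range(5)]
        assert all(r.part_file.exists() for r in reports)

    def test_reports_are_a_permutation_of_task_indices(self, tmp_path, store, ctx):
        lines = ["rsd-echo --text a", "rsd-fail", "rsd-echo --text b"] * 3
        runner = runner_of(tmp_path, *lines)
        cfg = ExecutorConfig(n_workers=3, task_timeout=30, max_attempts=2,
                             blacklist_threshold=100)
        reports = run_mapper(runner, cfg, store, ctx)
        assert sorted(r.task_index for r in reports) == list(range(len(lines)))

    def test_retry_cap_honored_for_permanent_failure(self, tmp_path, store, ctx):
        runner = runner_of(tmp_path, "rsd-fail")
        cfg = ExecutorConfig(n_workers=2, task_timeout=30, max_attempts=4,
                             blacklist_threshold=100)
        (report,) = run_mapper(runner, cfg, store, ctx)
        assert report.status == "failed"
        assert report.attempts == 4
        assert report.part_file is None

    def test_worker_blacklisted_after_consecutive_failures(self, tmp_path, store, ctx):
        runner = runner_of(tmp_path, *["rsd-fail-on-worker --worker 0"] * 8)
        cfg = ExecutorConfig(n_workers=2, task_timeout=30, max_attempts=4,
                             blacklist_threshold=4)
        reports = run_mapper(runner, cfg, store, ctx)
        assert all(r.status == "ok" for r in reports)
        log = store.get("log", "events.log").decode()
        blacklist_events = [l for l in log.splitlines() if l.endswith("blacklist")]
        assert len(blacklist_events) == 1
        assert blacklist_events[0].split("\t")[1] == "0"
        # after blacklisting, every success ran on the surviving worker
        assert {r.worker_id for r in reports} == {1}

    def test_timeout_kills_and_reports(self, tmp_path, store, ctx):
        runner = runner_of(tmp_path, "rsd-sleep --seconds 30")
        cfg = ExecutorConfig(n_workers=1, task_timeout=0.3, max_attempts=2,
                             blacklist_threshold=100)
        t0 = time.monotonic()
        (report,) = run_mapper(runner, cfg, store, ctx)
        assert report.status == "timeout"
        assert report.attempts == 2
        assert time.monotonic() - t0 < 10  # the sleeper was really killed

    def test_all_workers_blacklisted_aborts_with_partial_report(
        self, tmp_path, store, ctx
    ):
        runner = runner_of(tmp_path, *["rsd-fail"] * 6)
        cfg = ExecutorConfig(n_workers=1, task_timeout=30, max_attempts=100,
                             blacklist_threshold=2)
        with pytest.raises(ExecutorAbortError, match="blacklisted"):
            run_mapper(runner, cfg, store, ctx)


class TestResultStore:
    def test_put_get_round_trip(self, store):
        store.put("blast_result", "x/y.blast", b"payload\x00bytes")
        assert store.get("blast_result", "x/y.blast") == b"payload\x00bytes"

    def test_list_by_bucket_and_prefix(self, store):
        store.put("ortholog_results", "A__B__d0.5_e1e-05.orth", "x")
        store.put("ortholog_results", "A__C__d0.5_e1e-05.orth", "x")
        store.put("blast_result", "A__B.blast", "x")
        assert len(store.list("ortholog_results")) == 2
        assert store.list("ortholog_results", prefix="A__B") == [
            "A__B__d0.5_e1e-05.orth"
        ]

    def test_unknown_bucket_rejected(self, store):
        with pytest.raises(ValueError, match="bucket"):
            store.put("nope", "k", "v")


@pytest.fixture(scope="module")
def three_genomes():
    model = build_rate_model()
    dbs = []
    for k in range(3):
        A, _, _ = simulate_genome_pair(
            SimConfig(n_genes=6, t=0.2, length_range=(60, 120), seed=100 + k), model
        )
        dbs.append(format_genome(list(A), f"G{k}.aa"))
    return dbs


class TestTwoPhase:
    SETTINGS = param_grid((0.5,), (1e-5, 1e-10))

    def test_task_counts_and_outputs(self, tmp_path, three_genomes):
        store = ResultStore(tmp_path / "store")
        summary = run_two_phase(
            three_genomes, [], self.SETTINGS, FAST, store, tmp_path / "work"
        )
        assert summary.blast.n_tasks == 6  # 3 pairs x 2 directions
        assert summary.ortholog.n_tasks == 6  # 3 pairs x 2 settings
        assert summary.blast.ok == summary.ortholog.ok == 6
        assert len(store.list("blast_result")) == 6
        assert len(store.list("ortholog_results")) == 6

    def test_phase_two_refuses_incomplete_store(self, tmp_path, three_genomes):
        store = ResultStore(tmp_path / "store")
        names = [db.name for db in three_genomes]
        for db in three_genomes:
            save_genome(db, tmp_path / "work" / "genomes")
        ctx = ExecutionContext(
            genomes_root=tmp_path / "work" / "genomes",
            store_root=store.root,
            parts_dir=tmp_path / "work" / "parts",
        )
        run_blast_phase(names, [], self.SETTINGS, FAST, store, ctx)
        victim = store.list("blast_result")[0]
        store.delete("blast_result", victim)
        with pytest.raises(IncompleteStoreError, match=victim):
            run_ortholog_phase(names, [], self.SETTINGS, FAST, store, ctx)
        assert missing_hit_tables(names, [], store) == [victim]

    def test_phase_two_is_idempotent_and_resumable_across_processes(
        self, tmp_path, three_genomes
    ):
        store = ResultStore(tmp_path / "store")
        names = [db.name for db in three_genomes]
        for db in three_genomes:
            save_genome(db, tmp_path / "work" / "genomes")
        ctx = ExecutionContext(
            genomes_root=tmp_path / "work" / "genomes",
            store_root=store.root,
            parts_dir=tmp_path / "work" / "parts",
        )
        run_blast_phase(names, [], self.SETTINGS, FAST, store, ctx)

        # phase 2 in a *separate interpreter*, reading only the store
        script = (
            "from rsdlite.mapreduce_lite import *\n"
            "from rsdlite.rsdcore import param_grid\n"
            "from pathlib import Path\n"
            f"store = ResultStore({str(store.root)!r})\n"
            f"ctx = ExecutionContext(genomes_root=Path({str(ctx.genomes_root)!r}),\n"
            f"    store_root=Path({str(store.root)!r}),\n"
            f"    parts_dir=Path({str(tmp_path / 'work' / 'parts2')!r}))\n"
            f"summary, _ = run_ortholog_phase({names!r}, [], param_grid((0.5,), (1e-5, 1e-10)),\n"
            "    ExecutorConfig(n_workers=2), store, ctx)\n"
            "assert summary.ok == summary.n_tasks == 6\n"
        )
        subprocess.run([sys.executable, "-c", script], check=True)
        first = {
            key: store.get("ortholog_results", key)
            for key in store.list("ortholog_results")
        }
        assert len(first) == 6

        # re-running phase 2 in-process reproduces byte-identical outputs
        run_ortholog_phase(names, [], self.SETTINGS, FAST, store, ctx)
        second = {
            key: store.get("ortholog_results", key)
            for key in store.list("ortholog_results")
        }
        assert first == second
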