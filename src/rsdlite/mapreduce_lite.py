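"""A local, map-only, two-phase executor for the ortholog pipeline.

This module emulates a streaming map-reduce deployment on a single
machine, keeping the contract that made the original design fault
tolerant while replacing the distributed machinery with OS processes:

* **runner files** — plain-text files with one command per line; each
  line is one map task (there is no reducer stage);
* **worker pool** — ``n_workers`` slots, each task attempt runs in its
  own forked process so a hung task can really be killed;
* **timeout / retry** — an attempt exceeding ``task_timeout`` seconds is
  killed and recorded ``timeout``; attempts are retried up to
  ``max_attempts``;
* **blacklisting** — a worker accumulating ``blacklist_threshold``
  consecutive failures is removed from the pool; the run continues on
  the survivors and aborts only when no worker remains;
* **speculative execution** (off by default) — a task running past twice
  the median elapsed time of completed tasks may be duplicated on an
  idle worker, first finisher wins;
* **part files** — every successful task writes ``part-%05d``, and its
  payload is also copied into the appropriate bucket of a
  :class:`ResultStore` (``blast_result`` or ``ortholog_results``), so
  the search phase and the ortholog phase are decoupled: phase 2 can run
  in a later process as long as the store is complete.

Command grammar (whitespace-separated, no shell interpretation)::

    rsd-blast --query-genome A --db-genome B --evalue E
    rsd-ortho --genome-a A --genome-b B --divergence D --evalue E

plus four diagnostic commands used to exercise the executor contract:
``rsd-echo --text T``, ``rsd-sleep --seconds S``, ``rsd-fail``, and
``rsd-fail-on-worker --worker W``.
"""

from __future__ import annotations

import itertools
import multiprocessing as mp
import os
import time
import traceback
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import pairwise, rsdcore, seqio

__all__ = [
    "ResultStore",
    "RunnerFile",
    "TaskReport",
    "ExecutorConfig",
    "ExecutionContext",
    "ExecutorAbortError",
    "IncompleteStoreError",
    "parse_command",
    "generate_runner_file",
    "run_mapper",
    "run_blast_phase",
    "run_ortholog_phase",
    "run_two_phase",
    "missing_hit_tables",
    "PhaseSummary",
    "TwoPhaseSummary",
]

BUCKETS = ("log", "blast_result", "ortholog_results")

_POLL_INTERVAL = 0.01


class ResultStore:
    """A directory-backed store with three fixed buckets.

    Keys are relative paths inside a bucket; writes are atomic
    (temp file + rename) so concurrent task processes cannot interleave.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        for bucket in BUCKETS:
            (self.root / bucket).mkdir(parents=True, exist_ok=True)

    def _path(self, bucket: str, key: str) -> Path:
        if bucket not in BUCKETS:
            raise ValueError(f"unknown bucket {bucket!r}; expected one of {BUCKETS}")
        return self.root / bucket / key

    def put(self, bucket: str, key: str, data: bytes | str) -> None:
        if isinstance(data, str):
            data = data.encode()
        path = self._path(bucket, key)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_name(f".{path.name}.{os.getpid()}.tmp")
        tmp.write_bytes(data)
        tmp.replace(path)

    def get(self, bucket: str, key: str) -> bytes:
        return self._path(bucket, key).read_bytes()

    def exists(self, bucket: str, key: str) -> bool:
        return self._path(bucket, key).is_file()

    def delete(self, bucket: str, key: str) -> None:
        self._path(bucket, key).unlink()

    def list(self, bucket: str, prefix: str = "") -> list[str]:
        base = self.root / bucket
        keys = [
            str(p.relative_to(base))
            for p in base.rglob("*")
            if p.is_file() and not p.name.startswith(".")
        ]
        return sorted(k for k in keys if k.startswith(prefix))

    def append_log(self, worker: int | str, task: int | str, event: str) -> None:
        line = f"{time.time():.3f}\t{worker}\t{task}\t{event}\n"
        path = self._path("log", "events.log")
        with open(path, "a") as fh:
            fh.write(line)


# --- command grammar ---

_COMMANDS: dict[str, tuple[tuple[str, ...], dict[str, type]]] = {
    "rsd-blast": (("--query-genome", "--db-genome", "--evalue"),
                  {"--evalue": float}),
    "rsd-ortho": (("--genome-a", "--genome-b", "--divergence", "--evalue"),
                  {"--divergence": float, "--evalue": float}),
    "rsd-echo": (("--text",), {}),
    "rsd-sleep": (("--seconds",), {"--seconds": float}),
    "rsd-fail": ((), {}),
    "rsd-fail-on-worker": (("--worker",), {"--worker": int}),
}


def parse_command(line: str) -> tuple[str, dict[str, object]]:
    """Parse one runner-file line into (command name, argument mapping)."""
    tokens = line.split()
    if not tokens:
        raise ValueError("empty command line")
    name, rest = tokens[0], tokens[1:]
    if name not in _COMMANDS:
        raise ValueError(f"unknown command {name!r}")
    required, types = _COMMANDS[name]
    if len(rest) % 2 != 0:
        raise ValueError(f"{name}: options must come in --flag value pairs")
    args: dict[str, object] = {}
    for flag, value in zip(rest[::2], rest[1::2]):
        if flag not in required:
            raise ValueError(f"{name}: unexpected option {flag!r}")
        caster = types.get(flag, str)
        try:
            args[flag.lstrip("-").replace("-", "_")] = caster(value)
        except ValueError as exc:
            raise ValueError(f"{name}: bad value for {flag}: {value!r}") from exc
    missing = [f for f in required if f.lstrip("-").replace("-", "_") not in args]
    if missing:
        raise ValueError(f"{name}: missing required option(s) {missing}")
    return name, args


@dataclass(frozen=True)
class RunnerFile:
    """The mapper's input: one command per line, one line per map task."""

    path: Path
    phase: str
    lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.phase not in ("blast", "ortholog", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        for line in self.lines:
            parse_command(line)

    def __len__(self) -> int:
        return len(self.lines)

    @classmethod
    def write(cls, lines: Sequence[str], phase: str, path: str | Path) -> "RunnerFile":
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("".join(f"{l}\n" for l in lines))
        return cls(path=path, phase=phase, lines=tuple(lines))

    @classmethod
    def load(cls, path: str | Path, phase: str) -> "RunnerFile":
        path = Path(path)
        lines = tuple(l for l in path.read_text().splitlines() if l.strip())
        return cls(path=path, phase=phase, lines=lines)


def _compared_pairs(new: Sequence[str], existing: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered genome pairs to compare, deterministically sorted."""
    overlap = set(new) & set(existing)
    if overlap:
        raise ValueError(f"genomes listed as both new and existing: {sorted(overlap)}")
    if len(set(new)) != len(new) or len(set(existing)) != len(existing):
        raise ValueError("duplicate genome names")
    pairs = [tuple(sorted(p)) for p in itertools.combinations(new, 2)]
    pairs += [tuple(sorted((n, o))) for n in new for o in existing]
    return sorted(pairs)


def generate_runner_file(
    genome_names: Sequence[str],
    existing_names: Sequence[str],
    phase: str,
    settings: Sequence[rsdcore.ParamSetting],
    out: str | Path,
) -> RunnerFile:
    """Write the runner file for one phase.

    Phase ``blast``: two lines (one per search direction) for every
    compared pair, at the loosest E-value in ``settings`` so any setting
    can later filter the stored hits down.  Phase ``ortholog``: one line
    per compared pair per setting, settings in grid order.
    """
    pairs = _compared_pairs(genome_names, existing_names)
    lines: list[str] = []
    if phase == "blast":
        loose = max(s.evalue for s in settings) if settings else 1e-10
        for a, b in pairs:
            lines.append(f"rsd-blast --query-genome {a} --db-genome {b} --evalue {loose:g}")
            lines.append(f"rsd-blast --query-genome {b} --db-genome {a} --evalue {loose:g}")
    elif phase == "ortholog":
        for a, b in pairs:
            for s in settings:
                lines.append(
                    f"rsd-ortho --genome-a {a} --genome-b {b} "
                    f"--divergence {s.divergence:g} --evalue {s.evalue:g}"
                )
    else:
        raise ValueError(f"cannot generate runner file for phase {phase!r}")
    return RunnerFile.write(lines, phase, out)


# --- executor ---


@dataclass(frozen=True)
class ExecutorConfig:
    """Worker-pool policy: size, timeout, retries, blacklisting."""

    n_workers: int = 2
    task_timeout: float = 86400.0
    max_attempts: int = 4
    blacklist_threshold: int = 4
    speculative: bool = False

    def __post_init__(self) -> None:
        if min(self.n_workers, self.max_attempts, self.blacklist_threshold) < 1:
            raise ValueError("executor counts must be positive")
        if self.task_timeout <= 0:
            raise ValueError("task_timeout must be positive")


@dataclass(frozen=True)
class ExecutionContext:
    """Everything a task process needs to execute a pipeline command."""

    genomes_root: Path
    store_root: Path
    parts_dir: Path
    model_name: str = "JTT"
    alpha: float = 1.0
    gamma_categories: int = 4
    gap_open: int = 11
    gap_extend: int = 1
    max_hits: Optional[int] = 20


@dataclass
class TaskReport:
    """Outcome accounting for one runner-file line."""

    task_index: int
    status: str
    attempts: int
    worker_id: int
    elapsed: float
    part_file: Optional[Path] = None

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.part_file is not None):
            raise ValueError("part_file must be present iff status is 'ok'")


class ExecutorAbortError(RuntimeError):
    """All workers were blacklisted with tasks still pending."""

    def __init__(self, message: str, reports: list[TaskReport]):
        super().__init__(message)
        self.reports = reports


class IncompleteStoreError(RuntimeError):
    """Phase 2 was started against a store missing hit tables."""

    def __init__(self, missing: list[str]):
        super().__init__(
            "result store is missing precomputed hit tables: " + ", ".join(missing)
        )
        self.missing = missing


def execute_command(line: str, worker_id: int, ctx: ExecutionContext) -> str:
    """Run one pipeline command in-process and return its text payload."""
    name, args = parse_command(line)
    if name == "rsd-blast":
        qdb = seqio.load_genome(ctx.genomes_root / str(args["query_genome"]))
        sdb = seqio.load_genome(ctx.genomes_root / str(args["db_genome"]))
        scheme = pairwise.ScoringScheme.blosum62(ctx.gap_open, ctx.gap_extend)
        hitsets = pairwise.search_genome(
            qdb, sdb, scheme, float(args["evalue"]), max_hits=ctx.max_hits
        )
        return pairwise.hit_table_dumps(hitsets)
    if name == "rsd-ortho":
        from .evodist import build_rate_model

        I = seqio.load_genome(ctx.genomes_root / str(args["genome_a"]))
        J = seqio.load_genome(ctx.genomes_root / str(args["genome_b"]))
        scheme = pairwise.ScoringScheme.blosum62(ctx.gap_open, ctx.gap_extend)
        model = build_rate_model(ctx.model_name, ctx.alpha, ctx.gamma_categories)
        setting = rsdcore.ParamSetting(float(args["divergence"]), float(args["evalue"]))
        store = ResultStore(ctx.store_root)
        pairs = rsdcore.rsd_orthologs(
            I, J, setting, scheme, model, store=store, max_hits=ctx.max_hits
        )
        return rsdcore.ortholog_table_dumps(pairs)
    if name == "rsd-echo":
        return str(args["text"])
    if name == "rsd-sleep":
        time.sleep(float(args["seconds"]))
        return f"slept {args['seconds']}\n"
    if name == "rsd-fail":
        raise RuntimeError("scripted failure")
    if name == "rsd-fail-on-worker":
        if worker_id == int(args["worker"]):
            raise RuntimeError(f"scripted failure on worker {worker_id}")
        return "ok\n"
    raise AssertionError(f"unhandled command {name}")  # pragma: no cover


def store_target(line: str, task_index: int) -> tuple[str, str]:
    """The (bucket, key) a successful task's payload is copied to."""
    name, args = parse_command(line)
    if name == "rsd-blast":
        key = rsdcore.hit_table_key(str(args["query_genome"]), str(args["db_genome"]))
        return "blast_result", key
    if name == "rsd-ortho":
        setting = rsdcore.ParamSetting(float(args["divergence"]), float(args["evalue"]))
        key = rsdcore.ortholog_result_key(
            str(args["genome_a"]), str(args["genome_b"]), setting
        )
        return "ortholog_results", key
    return "log", f"task-output/{task_index:05d}.out"


def _child_main(line: str, worker_id: int, ctx: ExecutionContext, tmp_path: Path) -> None:
    try:
        payload = execute_command(line, worker_id, ctx)
        tmp_path.write_text(payload)
        os._exit(0)
    except BaseException:
        try:
            tmp_path.with_suffix(".err").write_text(traceback.format_exc())
        finally:
            os._exit(1)


@dataclass
class _Attempt:
    task_index: int
    worker_id: int
    proc: mp.process.BaseProcess
    started: float
    tmp_path: Path
    speculative: bool = False


@dataclass
class _TaskState:
    index: int
    line: str
    attempts: int = 0
    done: bool = False
    report: Optional[TaskReport] = None
    running: list = field(default_factory=list)


def run_mapper(
    runner: RunnerFile,
    config: ExecutorConfig,
    store: ResultStore,
    ctx: ExecutionContext,
) -> list[TaskReport]:
    """Execute every runner-file line on the worker pool.

    Returns one :class:`TaskReport` per line, ordered by task index.
    Raises :class:`ExecutorAbortError` when every worker has been
    blacklisted while tasks are still incomplete.
    """
    mp_ctx = mp.get_context("fork")
    parts_dir = Path(ctx.parts_dir)
    parts_dir.mkdir(parents=True, exist_ok=True)
    tmp_dir = parts_dir / ".attempts"
    tmp_dir.mkdir(exist_ok=True)

    tasks = [_TaskState(i, line) for i, line in enumerate(runner.lines)]
    pending: deque[int] = deque(t.index for t in tasks)
    worker_idle = {w: True for w in range(config.n_workers)}
    worker_fails = {w: 0 for w in range(config.n_workers)}
    blacklisted: set[int] = set()
    completed_elapsed: list[float] = []

    def spawn(task: _TaskState, worker: int, speculative: bool = False) -> None:
        tmp = tmp_dir / f"task{task.index:05d}-a{task.attempts}-w{worker}.out"
        proc = mp_ctx.Process(
            target=_child_main, args=(task.line, worker, ctx, tmp), daemon=True
        )
        proc.start()
        worker_idle[worker] = False
        task.running.append(
            _Attempt(task.index, worker, proc, time.monotonic(), tmp, speculative)
        )
        store.append_log(worker, task.index, "speculate" if speculative else "start")

    def finish_task(task: _TaskState, att: _Attempt, status: str, elapsed: float) -> None:
        part: Optional[Path] = None
        if status == "ok":
            payload = att.tmp_path.read_bytes()
            bucket, key = store_target(task.line, task.index)
            store.put(bucket, key, payload)
            part = parts_dir / f"part-{task.index:05d}"
            part.write_bytes(payload)
            completed_elapsed.append(elapsed)
        task.done = True
        task.report = TaskReport(
            task_index=task.index,
            status=status,
            attempts=task.attempts,
            worker_id=att.worker_id,
            elapsed=elapsed,
            part_file=part,
        )
        for other in task.running:  # cancel a surviving duplicate
            if other is not att and other.proc.is_alive():
                other.proc.terminate()
                other.proc.join()
                worker_idle[other.worker_id] = True
        task.running.clear()

    def register_failure(att: _Attempt, task: _TaskState, kind: str, elapsed: float) -> None:
        worker_fails[att.worker_id] += 1
        store.append_log(att.worker_id, task.index, kind)
        if worker_fails[att.worker_id] >= config.blacklist_threshold:
            blacklisted.add(att.worker_id)
            store.append_log(att.worker_id, task.index, "blacklist")
        if task.attempts < config.max_attempts:
            pending.append(task.index)
            store.append_log(att.worker_id, task.index, "retry")
        else:
            finish_task(task, att, kind if kind == "timeout" else "failed", elapsed)

    while True:
        incomplete = [t for t in tasks if not t.done]
        if not incomplete:
            break
        available = [w for w in range(config.n_workers) if w not in blacklisted]
        if not available:
            partial = [t.report for t in tasks if t.report is not None]
            raise ExecutorAbortError(
                f"all {config.n_workers} workers blacklisted with "
                f"{len(incomplete)} task(s) incomplete",
                partial,
            )

        # dispatch pending work (and speculative duplicates) to idle workers
        for w in available:
            if not worker_idle[w]:
                continue
            if pending:
                task = tasks[pending.popleft()]
                if task.done:
                    continue
                task.attempts += 1
                spawn(task, w)
            elif config.speculative and completed_elapsed:
                median = sorted(completed_elapsed)[len(completed_elapsed) // 2]
                now = time.monotonic()
                candidates = [
                    t
                    for t in tasks
                    if not t.done
                    and len(t.running) == 1
                    and now - t.running[0].started > 2 * median
                ]
                if candidates:
                    spawn(candidates[0], w, speculative=True)

        # reap finished and timed-out attempts
        progressed = False
        for task in tasks:
            for att in list(task.running):
                elapsed = time.monotonic() - att.started
                if not att.proc.is_alive():
                    att.proc.join()
                    worker_idle[att.worker_id] = True
                    task.running.remove(att)
                    progressed = True
                    if task.done:
                        continue
                    if att.proc.exitcode == 0:
                        worker_fails[att.worker_id] = 0
                        store.append_log(att.worker_id, task.index, "ok")
                        finish_task(task, att, "ok", elapsed)
                    else:
                        register_failure(att, task, "fail", elapsed)
                elif elapsed > config.task_timeout:
                    att.proc.terminate()
                    att.proc.join()
                    worker_idle[att.worker_id] = True
                    task.running.remove(att)
                    progressed = True
                    if not task.done:
                        register_failure(att, task, "timeout", elapsed)
        if not progressed:
            time.sleep(_POLL_INTERVAL)

    return [t.report for t in sorted(tasks, key=lambda t: t.index)]  # type: ignore[misc]


# --- two-phase workflow ---


@dataclass(frozen=True)
class PhaseSummary:
    phase: str
    n_tasks: int
    ok: int
    failed: int
    timeout: int

    @classmethod
    def from_reports(cls, phase: str, reports: Sequence[TaskReport]) -> "PhaseSummary":
        return cls(
            phase=phase,
            n_tasks=len(reports),
            ok=sum(r.status == "ok" for r in reports),
            failed=sum(r.status == "failed" for r in reports),
            timeout=sum(r.status == "timeout" for r in reports),
        )


@dataclass(frozen=True)
class TwoPhaseSummary:
    blast: PhaseSummary
    ortholog: PhaseSummary


def missing_hit_tables(
    new_names: Sequence[str], existing_names: Sequence[str], store: ResultStore
) -> list[str]:
    """Hit-table keys required for the ortholog phase but absent from the store."""
    missing = []
    for a, b in _compared_pairs(new_names, existing_names):
        for q, s in ((a, b), (b, a)):
            key = rsdcore.hit_table_key(q, s)
            if not store.exists("blast_result", key):
                missing.append(key)
    return missing


def run_blast_phase(
    new_names: Sequence[str],
    existing_names: Sequence[str],
    settings: Sequence[rsdcore.ParamSetting],
    config: ExecutorConfig,
    store: ResultStore,
    ctx: ExecutionContext,
    runner_path: str | Path | None = None,
) -> tuple[PhaseSummary, list[TaskReport]]:
    """Phase 1: compute and store all hit tables."""
    runner_path = runner_path or Path(ctx.parts_dir).parent / "blast_runner"
    runner = generate_runner_file(new_names, existing_names, "blast", settings, runner_path)
    parts = replace(ctx, parts_dir=Path(ctx.parts_dir) / "blast")
    reports = run_mapper(runner, config, store, parts)
    return PhaseSummary.from_reports("blast", reports), reports


def run_ortholog_phase(
    new_names: Sequence[str],
    existing_names: Sequence[str],
    settings: Sequence[rsdcore.ParamSetting],
    config: ExecutorConfig,
    store: ResultStore,
    ctx: ExecutionContext,
    runner_path: str | Path | None = None,
) -> tuple[PhaseSummary, list[TaskReport]]:
    """Phase 2: consume stored hit tables, write ortholog tables.

    May run in a later process invocation than phase 1; refuses to start
    when the store lacks any required hit table.
    """
    missing = missing_hit_tables(new_names, existing_names, store)
    if missing:
        raise IncompleteStoreError(missing)
    runner_path = runner_path or Path(ctx.parts_dir).parent / "ortho_runner"
    runner = generate_runner_file(
        new_names, existing_names, "ortholog", settings, runner_path
    )
    parts = replace(ctx, parts_dir=Path(ctx.parts_dir) / "ortholog")
    reports = run_mapper(runner, config, store, parts)
    return PhaseSummary.from_reports("ortholog", reports), reports


def run_two_phase(
    new: Sequence[seqio.GenomeDB],
    existing: Sequence[seqio.GenomeDB],
    settings: Sequence[rsdcore.ParamSetting],
    config: ExecutorConfig,
    store: ResultStore,
    work_dir: str | Path,
    **ctx_options,
) -> TwoPhaseSummary:
    """Run both phases end to end from in-memory genomes.

    Genomes are serialized under ``work_dir/genomes`` so task processes
    (and later invocations) can load them independently.
    """
    work_dir = Path(work_dir)
    genomes_root = work_dir / "genomes"
    for db in list(new) + list(existing):
        seqio.save_genome(db, genomes_root)
    ctx = ExecutionContext(
        genomes_root=genomes_root,
        store_root=store.root,
        parts_dir=work_dir / "parts",
        **ctx_options,
    )
    new_names = [db.name for db in new]
    existing_names = [db.name for db in existing]
    blast_summary, _ = run_blast_phase(new_names, existing_names, settings, config, store, ctx)
    ortho_summary, _ = run_ortholog_phase(new_names, existing_names, settings, config, store, ctx)
    return TwoPhaseSummary(blast=blast_summary, ortholog=ortho_summary)
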