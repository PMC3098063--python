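"""Workload accounting and cost projection for all-against-all ortholog runs.

With N genomes awaiting computation, O genomes already processed, and M
(divergence, E-value) parameter settings, the pipeline must run

    pairs(N, O)   = N(N-1)/2 + N*O              genome pairs
    f(N, O, M)    = pairs(N, O) * M             ortholog-estimation processes
    blast tasks   = pairs(N, O) * 2             (each pair searched both ways)

Times project as total core-hours spread over a fixed core count; costs
follow a constant-work model in which an instance fleet's total core-hours
is fixed, so fleets whose hourly rate per core is equal cost the same.
A small bundled table of instance types supports side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO
from typing import NamedTuple

import pandas as pd

__all__ = [
    "PlanInput",
    "InstanceSpec",
    "JobCounts",
    "pair_count",
    "process_count",
    "total_job_count",
    "time_projection",
    "instance_cost",
    "instance_hours",
    "load_instance_table",
    "plan_report",
]

HOURS_PER_YEAR = 8760.0


@dataclass(frozen=True)
class PlanInput:
    """Inputs to the workload model.

    N: genomes awaiting computation; O: genomes previously processed;
    M: number of parameter settings; hours_per_process: mean wall time of
    one ortholog process; cores: concurrently available cores.
    """

    N: int
    O: int = 0
    M: int = 1
    hours_per_process: float = 4.0
    cores: int = 300

    def __post_init__(self) -> None:
        if self.N < 0 or self.O < 0:
            raise ValueError("genome counts must be non-negative")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.hours_per_process <= 0 or self.cores < 1:
            raise ValueError("hours_per_process and cores must be positive")


@dataclass(frozen=True)
class InstanceSpec:
    """One fleet configuration: `count` instances for `hours` at a rate."""

    name: str
    cores: int
    rate_per_hour: float
    count: int
    hours: float

    def __post_init__(self) -> None:
        if min(self.cores, self.count) < 1 or self.rate_per_hour <= 0 or self.hours < 0:
            raise ValueError("instance spec fields must be positive")


class JobCounts(NamedTuple):
    blast: int
    ortholog: int
    total: int


def pair_count(N: int, O: int = 0) -> int:
    """Genome pairs to process: new-vs-new plus new-vs-existing."""
    if N < 0 or O < 0:
        raise ValueError("N and O must be non-negative")
    return N * (N - 1) // 2 + N * O


def process_count(plan: PlanInput) -> int:
    """f(N, O, M): ortholog-estimation processes over the whole grid."""
    return pair_count(plan.N, plan.O) * plan.M


def total_job_count(plan: PlanInput) -> JobCounts:
    """Map tasks by phase: bidirectional searches plus grid ortholog runs."""
    pairs = pair_count(plan.N, plan.O)
    blast = pairs * 2
    ortholog = pairs * plan.M
    return JobCounts(blast=blast, ortholog=ortholog, total=blast + ortholog)


def time_projection(
    processes: int, hours_per_process: float, cores: int
) -> tuple[float, float]:
    """(total wall hours, years to 1 decimal) on a fixed pool of cores."""
    if cores < 1:
        raise ValueError("cores must be >= 1")
    hours = processes * hours_per_process / cores
    return hours, round(hours / HOURS_PER_YEAR, 1)


def instance_cost(spec: InstanceSpec) -> int:
    """Fleet cost in whole dollars: count x hours x hourly rate."""
    return round(spec.count * spec.hours * spec.rate_per_hour)


def instance_hours(total_core_hours: float, count: int, cores_per_instance: int) -> float:
    """Hours a fleet needs to deliver a fixed amount of core-hours."""
    if count < 1 or cores_per_instance < 1:
        raise ValueError("count and cores_per_instance must be >= 1")
    return total_core_hours / (count * cores_per_instance)


def load_instance_table() -> list[InstanceSpec]:
    """The bundled instance-type comparison table."""
    text = resources.files("rsdlite.data").joinpath("instance_types.tsv").read_text()
    df = pd.read_csv(StringIO(text), sep="\t")
    return [
        InstanceSpec(
            name=row["name"],
            cores=int(row["cores"]),
            rate_per_hour=float(row["rate_per_hour"]),
            count=int(row["count"]),
            hours=float(row["hours"]),
        )
        for _, row in df.iterrows()
    ]


def plan_report(plan: PlanInput) -> str:
    """Human-readable workload summary, including both search-task
    conventions: bidirectional tasks (2 per pair) and unordered new-vs-
    existing cross pairs."""
    pairs = pair_count(plan.N, plan.O)
    cross = plan.N * plan.O
    jobs = total_job_count(plan)
    hours, years = time_projection(jobs.ortholog, plan.hours_per_process, plan.cores)
    lines = [
        f"genomes: {plan.N} new, {plan.O} existing ({plan.N + plan.O} total)",
        f"genome pairs:            {pairs:>12,}",
        f"  new-vs-existing cross: {cross:>12,}",
        f"search tasks (x2 dirs):  {jobs.blast:>12,}",
        f"ortholog tasks (M={plan.M}):  {jobs.ortholog:>12,}",
        f"total map tasks:         {jobs.total:>12,}",
        f"projected ortholog time: {hours:,.0f} h ({years} y) "
        f"at {plan.hours_per_process} h/process on {plan.cores} cores",
        "",
        "instance fleet comparison:",
    ]
    for spec in load_instance_table():
        lines.append(
            f"  {spec.name:<32} {spec.count:>3} x {spec.hours:>6.0f} h "
            f"@ ${spec.rate_per_hour:.3f}/h = ${instance_cost(spec):,}"
        )
    return "\n".join(lines)
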