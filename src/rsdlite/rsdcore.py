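"""The reciprocal smallest distance (RSD) ortholog decision procedure.

For a query protein i in genome I and a subject genome J:

1. search i against J and keep significant hits H;
2. globally align each hit with i and discard hits whose alignable
   fraction (ungapped columns / alignment length) falls below the
   divergence threshold;
3. estimate an ML distance for each survivor; the hit j with the smallest
   distance is the forward winner;
4. search j back against I, filter and score the hits L the same way
   (aligning against j, reusing the already-computed i<->j distance);
5. declare (i, j) orthologous iff i attains the minimum distance in L.

Reciprocity distinguishes orthologs from recent paralogs: a duplicate of
i that is closer to j than i steals the reciprocal minimum and vetoes
the pair.

The procedure runs over a grid of (divergence, E-value) settings, from
conservative to relaxed, producing one ortholog table per genome pair
per setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional, Sequence

from .evodist import RateModel, ml_distance
from .pairwise import (
    HitSet,
    ScoringScheme,
    alignable_fraction,
    global_align,
    hit_table_loads,
    local_search,
)
from .seqio import GenomeDB, ProteinSequence

__all__ = [
    "ParamSetting",
    "OrthologPair",
    "param_grid",
    "forward_best_hit",
    "reciprocal_confirm",
    "rsd_orthologs",
    "ortholog_table_dumps",
    "ortholog_table_loads",
    "ortholog_result_key",
    "hit_table_key",
    "DEFAULT_DIVERGENCES",
    "DEFAULT_EVALUES",
]

#: Conventional conservative-to-relaxed grid (3 x 4 = 12 settings).
DEFAULT_DIVERGENCES = (0.2, 0.5, 0.8)
DEFAULT_EVALUES = (1e-20, 1e-15, 1e-10, 1e-5)


@dataclass(frozen=True)
class ParamSetting:
    """One (divergence, evalue) run setting.

    ``divergence`` is the minimum alignable fraction of the global
    alignment; ``evalue`` is the search significance threshold.
    """

    divergence: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 < self.divergence <= 1:
            raise ValueError("divergence must lie in (0, 1]")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocally confirmed pair with its ML distance."""

    query_id: str
    subject_id: str
    distance: float
    setting: ParamSetting

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def param_grid(
    divergences: Sequence[float] = DEFAULT_DIVERGENCES,
    evalues: Sequence[float] = DEFAULT_EVALUES,
) -> list[ParamSetting]:
    """Cartesian product of settings, divergence-major, deterministic order."""
    if not divergences or not evalues:
        raise ValueError("divergences and evalues must be non-empty")
    return [ParamSetting(d, e) for d, e in product(divergences, evalues)]


class MissingCachedDistanceError(RuntimeError):
    """The forward cache lacks the i<->j distance the reciprocal step needs."""


def _filtered_distances(
    anchor: ProteinSequence,
    candidates: HitSet,
    db: GenomeDB,
    setting: ParamSetting,
    scheme: ScoringScheme,
    model: RateModel,
    reuse: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Divergence-filter hits and compute (or reuse) ML distances to anchor."""
    distances: dict[str, float] = {}
    for hit in candidates:
        if hit.evalue >= setting.evalue:
            continue
        aln = global_align(anchor, db[hit.subject_id], scheme)
        if alignable_fraction(aln) < setting.divergence:
            continue
        if reuse is not None and hit.subject_id in reuse:
            distances[hit.subject_id] = reuse[hit.subject_id]
        else:
            distances[hit.subject_id] = ml_distance(aln, model).t_hat
    return distances


def forward_best_hit(
    i: ProteinSequence,
    J: GenomeDB,
    setting: ParamSetting,
    scheme: ScoringScheme,
    model: RateModel,
    hits: HitSet | None = None,
    max_hits: int | None = 20,
) -> Optional[tuple[str, float, dict[str, float]]]:
    """Smallest-distance hit of i in J, or None when nothing survives.

    Returns ``(j_id, distance, cache)`` where ``cache`` maps every
    surviving subject id to its distance from i.  Ties on the minimum
    distance break toward the lexicographically smallest subject id.
    """
    if hits is None:
        hits = local_search(i, J, scheme, setting.evalue, max_hits=max_hits)
    cache = _filtered_distances(i, hits, J, setting, scheme, model)
    if not cache:
        return None
    j_id = min(cache, key=lambda s: (cache[s], s))
    return j_id, cache[j_id], cache


def reciprocal_confirm(
    i: ProteinSequence,
    j: ProteinSequence,
    I: GenomeDB,
    setting: ParamSetting,
    scheme: ScoringScheme,
    model: RateModel,
    forward_cache: Mapping[str, float],
    hits: HitSet | None = None,
    max_hits: int | None = 20,
) -> Optional[OrthologPair]:
    """Confirm (i, j) by the reciprocal search of j against genome I.

    The i<->j distance is reused from the forward cache (it is the same
    alignment problem); all other surviving hits of j get fresh distance
    estimates against j.  The pair is confirmed iff i survives the filter
    and attains the minimum distance — a tie involving i counts as
    confirmation, so exact duplicates do not veto the self-evident pair.
    """
    if j.id not in forward_cache:
        raise MissingCachedDistanceError(
            f"forward cache for query {i.id!r} has no distance to {j.id!r}"
        )
    if hits is None:
        hits = local_search(j, I, scheme, setting.evalue, max_hits=max_hits)
    distances = _filtered_distances(
        j, hits, I, setting, scheme, model, reuse={i.id: forward_cache[j.id]}
    )
    if i.id not in distances:
        return None
    if distances[i.id] <= min(distances.values()):
        return OrthologPair(i.id, j.id, forward_cache[j.id], setting)
    return None


def hit_table_key(query_genome: str, subject_genome: str) -> str:
    """Store key of the precomputed hit table for one search direction."""
    return f"{query_genome}__{subject_genome}.blast"


def rsd_orthologs(
    I: GenomeDB,
    J: GenomeDB,
    setting: ParamSetting,
    scheme: ScoringScheme,
    model: RateModel,
    store=None,
    max_hits: int | None = 20,
) -> list[OrthologPair]:
    """All reciprocal-smallest-distance orthologs between genomes I and J.

    When ``store`` (a :class:`rsdlite.mapreduce_lite.ResultStore`) is
    given, hit sets are read from its precomputed ``blast_result`` bucket
    instead of being searched on the fly; a missing table raises
    ``KeyError`` naming the (query-genome, subject-genome) entry.
    Output is sorted by query id; each query contributes at most one pair.
    """
    forward_tables: dict[str, HitSet] | None = None
    reverse_tables: dict[str, HitSet] | None = None
    if store is not None:
        forward_tables = _load_hit_tables(store, I.name, J.name)
        reverse_tables = _load_hit_tables(store, J.name, I.name)

    pairs: list[OrthologPair] = []
    for qid in sorted(I.records):
        i = I[qid]
        fwd_hits = None
        if forward_tables is not None:
            fwd_hits = forward_tables.get(qid, HitSet(qid, J.name, ()))
        fwd = forward_best_hit(i, J, setting, scheme, model, hits=fwd_hits, max_hits=max_hits)
        if fwd is None:
            continue
        j_id, _, cache = fwd
        rev_hits = None
        if reverse_tables is not None:
            rev_hits = reverse_tables.get(j_id, HitSet(j_id, I.name, ()))
        pair = reciprocal_confirm(
            i, J[j_id], I, setting, scheme, model, cache, hits=rev_hits, max_hits=max_hits
        )
        if pair is not None:
            pairs.append(pair)
    return pairs


def _load_hit_tables(store, query_genome: str, subject_genome: str) -> dict[str, HitSet]:
    key = hit_table_key(query_genome, subject_genome)
    if not store.exists("blast_result", key):
        raise KeyError(
            f"result store has no precomputed hit table blast_result/{key} "
            f"for ({query_genome}, {subject_genome})"
        )
    text = store.get("blast_result", key).decode()
    return hit_table_loads(text, subject_genome)


# --- ortholog-table serialization ---


def ortholog_result_key(genome_a: str, genome_b: str, setting: ParamSetting) -> str:
    """File name of one (genome pair, setting) ortholog table."""
    return f"{genome_a}__{genome_b}__d{setting.divergence:g}_e{setting.evalue:g}.orth"


def ortholog_table_dumps(pairs: Sequence[OrthologPair]) -> str:
    lines = ["query_id\tsubject_id\tdistance"]
    for p in pairs:
        lines.append(f"{p.query_id}\t{p.subject_id}\t{p.distance:.6f}")
    return "\n".join(lines) + "\n"


def ortholog_table_loads(text: str, setting: ParamSetting) -> list[OrthologPair]:
    pairs = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        q, s, d = line.split("\t")
        pairs.append(OrthologPair(q, s, float(d), setting))
    return pairs
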