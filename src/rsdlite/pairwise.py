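"""Local search and global alignment of protein sequences.

This module provides the two sequence-comparison stages of the ortholog
pipeline:

* :func:`local_search` — optimal Smith–Waterman local alignment of a query
  against every record of a genome database, with Karlin–Altschul-style
  E-values, standing in for a BLASTP search;
* :func:`global_align` — optimal Needleman–Wunsch global alignment with
  affine gaps, standing in for a clustalW pairwise alignment, whose
  :func:`alignable_fraction` feeds the pipeline's divergence filter.

Dynamic programming is delegated to Biopython's ``PairwiseAligner`` (exact,
C-implemented); this module owns the scoring scheme, the E-value model, hit
filtering/ordering, and the alignment container.

E-values use the *ungapped* Karlin–Altschul scale parameter ``lambda_u``
(computed exactly from the matrix and background frequencies) applied to
gapped scores with a fixed prefactor ``K_u``.  This is a deliberate,
documented approximation: it is self-contained, strictly monotone in the
raw score, and keeps the significance threshold adjustable.  A raw-score
cutoff mode is available where exact significance is not wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from ._paml import load_dat
from .seqio import AMINO_ACIDS, GenomeDB, ProteinSequence

__all__ = [
    "ScoringScheme",
    "Hit",
    "HitSet",
    "PairwiseAlignment",
    "local_search",
    "search_genome",
    "global_align",
    "alignable_fraction",
    "hit_table_dumps",
    "hit_table_loads",
]

#: Alphabet used by the aligner: canonical residues plus unknown.
_ALIGN_ALPHABET = AMINO_ACIDS + "X"


def _ungapped_lambda(matrix: np.ndarray, pi: np.ndarray) -> float:
    """Solve sum_ij pi_i pi_j exp(lambda * s_ij) = 1 for lambda > 0."""
    outer = np.outer(pi, pi)

    def f(lam: float) -> float:
        return float(np.sum(outer * np.exp(lam * matrix)) - 1.0)

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - guarded by expected-score check
            raise ValueError("no positive Karlin-Altschul lambda found")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and E-value parameters.

    ``matrix`` is a symmetric 20x20 integer score matrix over
    :data:`rsdlite.seqio.AMINO_ACIDS`.  A gap of length L costs
    ``gap_open + gap_extend * L`` (NCBI convention).  ``lambda_u`` and
    ``K_u`` parameterize E = K_u * m * n * exp(-lambda_u * S).
    """

    matrix: np.ndarray
    gap_open: int
    gap_extend: int
    background: np.ndarray
    lambda_u: float
    K_u: float
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (20, 20) or not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric 20x20")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        pi = np.asarray(self.background, dtype=float)
        expected = float(pi @ m @ pi)
        if expected >= 0:
            raise ValueError(
                f"expected score {expected:.3f} under background frequencies must "
                "be negative for E-value theory to apply"
            )
        check = float(np.sum(np.outer(pi, pi) * np.exp(self.lambda_u * m)))
        if abs(check - 1.0) > 1e-6:
            raise ValueError("lambda_u does not satisfy the Karlin-Altschul identity")
        if self.K_u <= 0:
            raise ValueError("K_u must be positive")

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        gap_open: int,
        gap_extend: int,
        background: np.ndarray | None = None,
        K_u: float = 0.13,
        name: str = "custom",
    ) -> "ScoringScheme":
        """Build a scheme, solving for ``lambda_u`` numerically.

        ``background`` defaults to the JTT stationary frequencies — the same
        composition model used for distance estimation downstream.
        """
        if background is None:
            _, background = load_dat("jtt")
        matrix = np.asarray(matrix, dtype=float)
        background = np.asarray(background, dtype=float)
        expected = float(background @ matrix @ background)
        if expected >= 0:
            raise ValueError(
                f"expected score {expected:.3f} under background frequencies must "
                "be negative for E-value theory to apply"
            )
        lam = _ungapped_lambda(matrix, background)
        return cls(
            matrix=matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
            background=np.asarray(background, dtype=float),
            lambda_u=lam,
            K_u=K_u,
            name=name,
        )

    @classmethod
    def blosum62(cls, gap_open: int = 11, gap_extend: int = 1) -> "ScoringScheme":
        """BLOSUM62 with the BLASTP default affine gap penalties."""
        full = substitution_matrices.load("BLOSUM62")
        m = np.array(
            [[full[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
        )
        return cls.from_matrix(m, gap_open, gap_extend, name="BLOSUM62")

    def _biopython_matrix(self):
        """Matrix over residues+X with X scoring 0 against everything."""
        n = len(_ALIGN_ALPHABET)
        arr = substitution_matrices.Array(alphabet=_ALIGN_ALPHABET, dims=2)
        data = np.zeros((n, n))
        data[:20, :20] = self.matrix
        arr[:, :] = data
        return arr

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        """A configured Biopython aligner ('local' or 'global')."""
        al = Align.PairwiseAligner()
        al.substitution_matrix = self._biopython_matrix()
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        al.mode = mode
        return al

    def evalue(self, score: float, m: int, n: int) -> float:
        """Expected number of chance hits at or above ``score``."""
        return self.K_u * m * n * math.exp(-self.lambda_u * score)


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    raw_score: int
    evalue: float

    def __post_init__(self) -> None:
        if self.raw_score < 0 or self.evalue <= 0:
            raise ValueError("hit requires raw_score >= 0 and evalue > 0")


@dataclass(frozen=True)
class HitSet:
    """Significant matches of one query against one genome, best first."""

    query_id: str
    subject_genome: str
    hits: tuple[Hit, ...]

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.hits, key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
        )
        object.__setattr__(self, "hits", ordered)
        subjects = [h.subject_id for h in ordered]
        if len(subjects) != len(set(subjects)):
            raise ValueError("duplicate subject_id in hit set")

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences; '-' marks a gap."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    length: int = field(init=False)
    matched_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        object.__setattr__(self, "length", len(self.aligned_a))
        matched = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column gapped in both rows")
            if x != "-" and y != "-":
                matched += 1
        object.__setattr__(self, "matched_columns", matched)

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


def local_search(
    query: ProteinSequence,
    db: GenomeDB,
    scheme: ScoringScheme,
    evalue_threshold: float = 1e-10,
    max_hits: int | None = 20,
    min_raw_score: int | None = None,
) -> HitSet:
    """Smith–Waterman search of ``query`` against every record of ``db``.

    A record is retained when its optimal local-alignment score S gives
    E = K_u * m * n * exp(-lambda_u * S) below ``evalue_threshold`` (with
    m the query length and n the total residue count of the database).
    When ``min_raw_score`` is given it replaces the E-value test.  At most
    ``max_hits`` best hits are kept (``None`` for no limit); ordering is
    ascending E-value, then descending score, then subject id.
    """
    if len(query) == 0:
        raise ValueError("query has length 0")
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be positive")
    aligner = scheme.aligner("local")
    m, n = len(query), db.total_residues
    hits = []
    for rec in db:
        score = int(round(aligner.score(query.seq, rec.seq)))
        if score <= 0:
            continue
        ev = scheme.evalue(score, m, n)
        keep = score >= min_raw_score if min_raw_score is not None else ev < evalue_threshold
        if keep:
            hits.append(Hit(query.id, rec.id, score, ev))
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    if max_hits is not None:
        hits = hits[:max_hits]
    return HitSet(query.id, db.name, tuple(hits))


def search_genome(
    query_db: GenomeDB,
    subject_db: GenomeDB,
    scheme: ScoringScheme,
    evalue_threshold: float = 1e-10,
    max_hits: int | None = 20,
) -> list[HitSet]:
    """Search every record of ``query_db`` against ``subject_db`` (id order)."""
    return [
        local_search(query_db[qid], subject_db, scheme, evalue_threshold, max_hits)
        for qid in sorted(query_db.records)
    ]


def global_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment with affine gaps.

    Among co-optimal alignments the aligner's first traceback is returned,
    which is deterministic for fixed inputs.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot globally align an empty sequence")
    aligner = scheme.aligner("global")
    aln = aligner.align(a.seq, b.seq)[0]
    return PairwiseAlignment(a.id, b.id, str(aln[0]), str(aln[1]))


def alignable_fraction(aln: PairwiseAlignment) -> float:
    """Fraction of alignment columns in which neither sequence has a gap."""
    if aln.length == 0:
        raise ValueError("empty alignment")
    return aln.matched_columns / aln.length


# --- hit-table serialization (tab-delimited, one file per genome pair) ---

_HIT_HEADER = "query_id\tsubject_id\traw_score\tevalue"


def hit_table_dumps(hitsets: Sequence[HitSet]) -> str:
    """Serialize per-query hit sets for one (query-genome, subject-genome) pair."""
    lines = [_HIT_HEADER]
    for hs in hitsets:
        for h in hs:
            lines.append(f"{h.query_id}\t{h.subject_id}\t{h.raw_score}\t{h.evalue:.6e}")
    return "\n".join(lines) + "\n"


def hit_table_loads(text: str, subject_genome: str) -> dict[str, HitSet]:
    """Parse a hit table back into a mapping query_id -> HitSet."""
    by_query: dict[str, list[Hit]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line == _HIT_HEADER:
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"hit table line {lineno}: expected 4 columns")
        q, s, score, ev = parts
        by_query.setdefault(q, []).append(Hit(q, s, int(score), float(ev)))
    return {
        q: HitSet(q, subject_genome, tuple(hits)) for q, hits in by_query.items()
    }
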