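"""Forward simulation of genome pairs with known ortholog/paralog truth.

Genes evolve under exactly the substitution model used for inference
(:mod:`rsdlite.evodist`): ancestral residues are drawn from the model's
stationary frequencies, each site gets a rate drawn from the model's
discrete-gamma categories, and descendants evolve independently for t/2
along each branch, so an ortholog pair is separated by a total distance t.

Family structure per gene:

* **ortholog** — one ancestral gene, one descendant copy in each genome;
* **paralog** — additionally, a duplicate of the ancestor evolves for an
  extra ``t_dup`` and lands in genome A; its true separation from the B
  copy is ``t + t_dup``, so it is a decoy the reciprocal test must reject;
* **unrelated** — a fresh gene present in only one genome (alternating).

No indels are simulated: related sequences stay equal length, keeping the
simulation exactly inside the inference model so that distance recovery
is a clean test.  The divergence filter is exercised separately with
constructed fragment fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evodist import RateModel, transition_matrix
from .rsdcore import OrthologPair
from .seqio import AMINO_ACIDS, GenomeDB, ProteinSequence, format_genome

__all__ = [
    "SimConfig",
    "TruthTable",
    "ScoreReport",
    "simulate_genome_pair",
    "evolve_sequence",
    "score_against_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome pair.

    t is the true ortholog separation (substitutions/site); paralogs are
    ancestral duplicates evolved an extra ``t_dup``; ``unrelated_fraction``
    of genes appear in only one genome; alpha is the gamma shape used both
    to simulate and (by default) to infer.
    """

    n_genes: int = 100
    length_range: tuple[int, int] = (100, 400)
    t: float = 0.3
    paralog_fraction: float = 0.0
    t_dup: float = 0.05
    unrelated_fraction: float = 0.0
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.t < 0 or self.t_dup < 0:
            raise ValueError("divergences must be non-negative")
        for f in (self.paralog_fraction, self.unrelated_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.paralog_fraction + self.unrelated_fraction > 1:
            raise ValueError("paralog_fraction + unrelated_fraction must be <= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth relations between the two simulated genomes."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id_in_A", "id_in_B", "relation", "true_t"]
        )
    )

    def orthologs(self) -> set[tuple[str, str]]:
        sub = self.frame[self.frame.relation == "ortholog"]
        return set(zip(sub.id_in_A, sub.id_in_B))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.frame)


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a row-stochastic probability matrix."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    return (u[:, None] > cum).sum(axis=1)


def evolve_sequence(
    ancestor: np.ndarray,
    site_rates: np.ndarray,
    branch_t: float,
    model: RateModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve residue indices along one branch, site rates held fixed."""
    child = ancestor.copy()
    if branch_t == 0:
        return child
    for rate in np.unique(site_rates):
        sites = np.nonzero(site_rates == rate)[0]
        P = transition_matrix(model, branch_t, float(rate))
        child[sites] = _sample_categorical(rng, P[ancestor[sites]])
    return child


def _to_seq(indices: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in indices)


def simulate_genome_pair(
    cfg: SimConfig, model: RateModel
) -> tuple[GenomeDB | None, GenomeDB | None, TruthTable]:
    """Simulate genomes A and B plus their ground-truth relation table.

    Deterministic given ``cfg.seed``.  Returns ``(None, None, empty)`` for
    the degenerate zero-gene configuration.  The model's own discrete
    category rates supply the per-site rates, so simulation and inference
    share one model exactly.
    """
    if cfg.n_genes == 0:
        return None, None, TruthTable()
    rng = np.random.default_rng(cfg.seed)
    n_par = int(round(cfg.n_genes * cfg.paralog_fraction))
    n_unrel = int(round(cfg.n_genes * cfg.unrelated_fraction))
    n_orth = cfg.n_genes - n_par - n_unrel

    a_records: list[ProteinSequence] = []
    b_records: list[ProteinSequence] = []
    rows: list[dict] = []
    width = len(str(cfg.n_genes))

    for g in range(cfg.n_genes):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        ancestor = _sample_categorical(
            rng, np.tile(model.pi, (length, 1))
        )
        site_rates = model.category_rates[rng.integers(0, model.K, size=length)]
        a_id, b_id = f"A{g:0{width}d}", f"B{g:0{width}d}"

        if g < n_orth + n_par:  # an ortholog family (maybe with a duplicate)
            half = cfg.t / 2.0
            seq_a = evolve_sequence(ancestor, site_rates, half, model, rng)
            seq_b = evolve_sequence(ancestor, site_rates, half, model, rng)
            a_records.append(ProteinSequence(a_id, _to_seq(seq_a)))
            b_records.append(ProteinSequence(b_id, _to_seq(seq_b)))
            rows.append(
                dict(id_in_A=a_id, id_in_B=b_id, relation="ortholog", true_t=cfg.t)
            )
            if g >= n_orth:  # duplicate the ancestor into genome A
                dup = evolve_sequence(
                    ancestor, site_rates, half + cfg.t_dup, model, rng
                )
                dup_id = a_id + "p"
                a_records.append(ProteinSequence(dup_id, _to_seq(dup)))
                rows.append(
                    dict(
                        id_in_A=dup_id,
                        id_in_B=b_id,
                        relation="paralog",
                        true_t=cfg.t + cfg.t_dup,
                    )
                )
        else:  # unrelated: present in one genome only, alternating
            if g % 2 == 0:
                a_records.append(ProteinSequence(a_id, _to_seq(ancestor)))
                rows.append(
                    dict(id_in_A=a_id, id_in_B="", relation="none", true_t=np.nan)
                )
            else:
                b_records.append(ProteinSequence(b_id, _to_seq(ancestor)))
                rows.append(
                    dict(id_in_A="", id_in_B=b_id, relation="none", true_t=np.nan)
                )

    truth = TruthTable(pd.DataFrame(rows))
    A = format_genome(a_records, "A.aa") if a_records else None
    B = format_genome(b_records, "B.aa") if b_records else None
    return A, B, truth


@dataclass(frozen=True)
class ScoreReport:
    """Recovery of the true ortholog set by a list of confirmed pairs."""

    sensitivity: float
    precision: float
    n_true: int
    n_confirmed: int
    n_correct: int
    precision_defined: bool

    def as_tuple(self) -> tuple[float, float]:
        return self.sensitivity, self.precision


def score_against_truth(
    pairs: Sequence[OrthologPair], truth: TruthTable
) -> ScoreReport:
    """Sensitivity and precision of confirmed pairs against the truth table.

    Confirmed pairs matching a paralog or unrelated row (or nothing at
    all) count against precision.  With no confirmed pairs, precision is
    undefined and reported as 1.0 with ``precision_defined=False``.
    """
    true_orth = truth.orthologs()
    confirmed = {(p.query_id, p.subject_id) for p in pairs}
    correct = confirmed & true_orth
    sens = len(correct) / len(true_orth) if true_orth else 0.0
    if confirmed:
        prec, defined = len(correct) / len(confirmed), True
    else:
        prec, defined = 1.0, False
    return ScoreReport(
        sensitivity=sens,
        precision=prec,
        n_true=len(true_orth),
        n_confirmed=len(confirmed),
        n_correct=len(correct),
        precision_defined=defined,
    )
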