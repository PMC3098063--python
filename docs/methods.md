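# Methods

This note documents the models, numerical choices, and design decisions
behind rsdlite, and states what the simulation-based tests do and do not
demonstrate about real data.

## The ortholog decision procedure

Orthology between genomes *I* and *J* is decided per query protein *i*
by the reciprocal smallest *distance* criterion rather than reciprocal
best hit: significant search hits of *i* in *J* are globally aligned
with *i*, hits covering too little of the alignment are discarded, a
maximum-likelihood evolutionary distance is estimated for each survivor,
and the closest hit *j* must in turn find *i* as its closest surviving
hit in the reciprocal direction. Two tie-break rules are fixed for
determinism: the forward minimum breaks toward the lexicographically
smallest subject id, and a reciprocal tie *involving i* counts as
confirmation (so identical duplicates cannot veto the self-evident
pair). The reciprocal step reuses exactly one cached quantity — the
*i*↔*j* distance, which is the same alignment problem in either
direction (the model is time-reversible) — and recomputes everything
else. Each query yields at most one pair per parameter setting;
many-to-one subject assignments are allowed.

The procedure runs over a grid of settings. Defaults are divergence ∈
{0.2, 0.5, 0.8} × E-value ∈ {1e-20, 1e-15, 1e-10, 1e-5}, i.e. 12
settings spanning conservative to relaxed; both axes are ordinary run
parameters, not constants.

## Search and alignment

Both aligners compute exact optimal alignments (no heuristic seeding);
the dynamic programming itself is delegated to Biopython's
`PairwiseAligner`, configured so a gap of length L costs
`gap_open + gap_extend·L` (defaults 11/1, BLOSUM62). Independent
brute-force Gotoh implementations in the test suite verify both modes.
Among co-optimal global alignments the aligner's first traceback is
used; it is deterministic for fixed inputs, which is the property the
pipeline needs (the score, and therefore every downstream decision, is
identical across co-optima except for rare alignable-fraction ties at
the filter boundary).

Unknown residues (`X`, to which the rare ambiguity codes B/Z/J/U/O are
mapped on input) score 0 against everything during alignment and are
excluded as missing data from distance estimation. Stop characters are
stripped on read with a warning.

**E-values.** Significance uses Karlin–Altschul statistics
E = K·m·n·e^(−λS) with *m* the query length and *n* the total residue
count of the subject genome. λ is solved exactly from the scoring
matrix and background frequencies (the identity
Σᵢⱼ πᵢπⱼ·e^(λ·sᵢⱼ) = 1; background defaults to the JTT stationary
frequencies, the same composition model used downstream). K is fixed at
0.13, a literature-typical value for ungapped BLOSUM62 statistics, and
the *ungapped* (λ, K) pair is applied to *gapped* scores. This is a
deliberate approximation: it keeps the package self-contained, is
strictly monotone in the raw score, and preserves an adjustable
threshold — but the absolute E-value scale is conservative relative to
gapped BLAST statistics. Where exact significance calibration matters,
`local_search` accepts a raw-score cutoff instead. Searches keep at most
`max_hits` (default 20) best hits per query; the decision procedure only
ever needs the near-smallest-distance candidates, and the cap can be
lifted (`max_hits=None`).

## Maximum-likelihood distance

The estimator assumes a reversible empirical rate matrix
Qᵢⱼ = Sᵢⱼ·πⱼ scaled to one expected substitution per site, so *t* is in
substitutions/site. Shipped models: JTT (default), Dayhoff, and Poisson
(uniform; admits the 20-state Jukes–Cantor closed form
t = −(19/20)·ln(1 − (20/19)·p̂) used as an oracle). The exchangeability
and frequency tables are plain-text files in the classic dat layout.

Among-site rate variation is gamma-distributed with shape α,
discretized into K equal-probability categories represented by their
means (computed via the incomplete-gamma identity and renormalized to
mean exactly 1). Defaults α = 1.0, K = 4. α properly depends on the
phylogenetic depth of the comparison; no automatic mapping is attempted
— it is a per-run parameter. α → ∞ or K = 1 recovers the homogeneous
model.

The likelihood of an alignment is a product over columns of
π_a·(1/K)·Σₖ P(a→b | t·rₖ), with P(·) computed from a cached
eigendecomposition of the symmetrized generator (numerically stable for
reversible Q; entries clipped to [0,1] against roundoff). Columns with a
gap or unknown residue in either row are deleted. Optimization is
bounded Brent over t ∈ [0, t_max] (defaults t_max = 20, xatol = 1e-6),
with an explicit check of the t = 0 boundary (identical sequences);
estimates landing at t_max are flagged `converged=False`. The estimator
agrees with a 2000-point grid search within one grid step and with R
phangorn's independent `dist.ml` (JTT, with and without gamma) to
better than 0.1%.

## The simulator and what the tests show

`simgen` evolves gene families forward under exactly the inference
model: ancestral residues from π, per-site rates drawn from the model's
own K discrete categories, and two descendant copies evolved t/2 each.
Paralog decoys are ancestral duplicates evolved an extra `t_dup` into
genome A; unrelated genes are fresh draws present in one genome only.
Gene lengths are uniform on 100–400 residues by default — typical of
bacterial proteins. Defaults for the recovery experiments (100 genes,
t = 0.3, divergence 0.5, E < 1e-5) represent a moderately diverged
bacterial pair where near-complete recovery is the correct outcome.

Deliberately absent: indels within families (related sequences stay
equal length, so the divergence filter is exercised with constructed
fragment fixtures instead), gene-family birth/death dynamics,
composition heterogeneity across genes, and any model misspecification.
Passing the recovery tests therefore shows the pipeline is *correct
under its own model assumptions* — it does not measure accuracy on real
proteomes, where alignment error and model misfit dominate.

One empirical caveat the tests respect: an ancestral duplicate only
t_dup ≈ 0.05 substitutions/site farther from the ortholog is within ML
estimation noise at 100–400 residues, so the reciprocal veto of such a
decoy is not deterministic. The packaged precision property uses a
resolvable duplication depth (t_dup comparable to t); the sharper
recent-paralog veto (a decoy very close to *j*) is asserted with a
constructed fixture where the margin is large.

## The executor

The executor reproduces, on one machine, the contract of a streaming
map-only cluster job. Runner files hold one whitespace-separated
command per line; each line is one map task; there is no reducer. Each
attempt runs in a forked OS process so a hung task can genuinely be
killed at `task_timeout` (default 86400 s — sized so that the largest
genome-pair comparisons finish while zombie jobs are still reaped;
tests use sub-second timeouts). Failed or timed-out attempts are
retried up to `max_attempts` (default 4); a worker with
`blacklist_threshold` (default 4) consecutive failures leaves the pool;
the run aborts only when no worker remains. Speculative duplication of
slow tasks (past 2× the median completed elapsed time) is implemented
but off by default — with highly variable task durations it wastes
capacity. Every success writes a `part-%05d` file and copies its
payload into the result store.

The two phases are decoupled through the store (buckets `log/`,
`blast_result/`, `ortholog_results/`): phase 1 persists one hit table
per ordered genome pair, computed at the *loosest* E-value in the
settings grid so that any setting can filter the stored hits down;
phase 2 reads only the store and may run in a different process at any
later time, refusing to start (naming the missing tables) if the store
is incomplete. Phase 2 is idempotent: reruns produce byte-identical
outputs.

## Workload model

Plans count N·(N−1)/2 + N·O genome pairs (N new, O previously
processed), ×2 for bidirectional search tasks and ×M for ortholog
tasks over M settings. Both search-task conventions are reported —
bidirectional tasks and the unordered new-vs-existing cross-pair count
— since both appear in practice. Cost projection uses a constant-work
model: a fleet's total core-hours is fixed, so cost depends only on the
hourly rate per core, which is why single-core and 8-core fleets with
proportional rates cost the same. Costs are rounded to whole dollars;
years to one decimal (8760 h/year).

## Known limitations

- E-value calibration is approximate (above); comparisons across
  scoring schemes should use raw-score mode.
- Distances are point estimates; no standard errors or among-pair α
  estimation.
- The core decides orthology per genome *pair*; clustering across >2
  genomes and phylogenetic-profile assembly are out of scope.
- The executor is single-host by design; it emulates the scheduling
  contract, not distributed storage or network failure modes.
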