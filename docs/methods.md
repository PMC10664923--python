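# Methods

This note documents the statistical model, the numerical and design
choices, what the synthetic-data generator does and does not emulate,
and the known limitations of the package.

## Data model and normalization

Input histories are (patient, code, date) rows. Before any statistic is
computed, every code is aggregated to the configured analysis level of
the vocabulary and deduplicated to its **first occurrence** per patient:
diagnoses are treated as one-time onset events, so repeat billing of the
same code cannot inflate pair counts. All date arithmetic is in whole
days on proleptic-Gregorian ordinals; the duration tokens map as 1M =
30.5 days and 1Y = 365.25 days, so the default window "6M–5Y" is
183–1826 days inclusive at both ends.

Hierarchy levels are numbered by depth from the chapter: chapter 0,
block 1, three-character category 2, subcategory 3. The default analysis
level 2 therefore works at three-character-category granularity. In CCSR
mode the analysis level is the category table itself. Treatment codes
(prefix `TX:`) sit outside the hierarchy and pass through level mapping
unchanged. Codes are normalized (uppercase, dots stripped) before
lookup, since real extracts mix `C67.2` and `C672`. ICD-9 codes are
carried as opaque codes unless a crosswalk table is supplied; without
one they simply remain distinct events.

Chapter exclusions ship as a data file
(`trajmine/data/default_exclusions.json`): pregnancy/childbirth,
perinatal conditions, external causes, and Z codes, with the
bladder-cancer history code whitelisted as a cohort anchor. Exclusion is
closed under descendants; the whitelist is checked first, so an anchor
inside an excluded chapter still participates.

## Matched-sampling relative risk

Patients are stratified on (sex, birth-year bin); the observed
birth-year range is split into `nofAgeGroups` equal-width bins (default
10) and boundary years clamp into the last bin. Binning birth years
rather than age-at-event gives a static stratum usable for sampling.
Patients with unknown sex or birth year never enter matched sampling.

For a pair (A, B), each sampling iteration draws, per stratum, as many
non-exposed patients (without replacement) as the stratum holds exposed
patients. A stratum short of controls is truncated symmetrically: the
exposed side is cut to the number of available controls and the
shortfall recorded. Counting "B after not-A" needs a time anchor that a
non-exposed patient does not have; each sampled control inherits the A
date of the exposed patient it is **rank-matched** with inside its
stratum. This makes the comparison count well defined and exactly
reproducible, and its expectation enumerable in closed form (which the
test suite exploits as an oracle). The empirical p-value uses the
add-one (Davison–Hinkley) estimator, p = (1 + #{draws with comparison
rate ≥ exposed rate}) / (iterations + 1), so p ∈ [1/(iter+1), 1] and is
never exactly zero. A comparison rate of zero with a positive exposed
rate stores RR = +inf as a sentinel.

Pair selection requires RR > 1, p < α (default α = 0.05 on the raw
empirical p-values), and at least `minPatients` exposed patients showing
the windowed A-then-B sequence. Benjamini–Hochberg and Bonferroni
corrections are available (`correction="bh"`/`"bonferroni"`) but the
default is **no correction**: the empirical p-values are floored at
1/(iterations+1), and at practical iteration counts (a few hundred) that
floor sits above the per-rank thresholds step-up procedures need over
hundreds of pairs, so a corrected default would silently reject
everything. Users wanting family-wise control should raise `iterations`
accordingly before enabling a correction.

When both orientations of a pair have RR > 1, an exact two-sided
binomial test (integer arithmetic, probability 0.5) on the windowed
first-occurrence counts decides the direction; only a significantly
dominant orientation survives, exact ties drop both.

Every pair draws from its own random stream derived from (seed, A, B)
via a hash, so results are bit-identical no matter how the pair space is
chunked across workers — the parallelism contract is "independent work
units, order-free merge", and the sequential driver is its reference
implementation.

The prefilter admits only ordered pairs whose raw windowed co-occurrence
count already meets `minPatients`; cheaper than a sampling experiment
and provably without false negatives for the later selection rule.

## Trajectory building

Selected pairs seed a worklist of partial trajectories. A partial
[..., Y] extends with every selected pair (Y, Z), Z not yet in the
sequence, provided the extension keeps at least `minPatients`
supporters; extension copies the partial, since one partial may extend
several ways. A patient supports a sequence iff its per-code first
occurrences are strictly increasing with every consecutive gap inside
the window. Support is anti-monotone under extension (asserted at run
time), which makes the supporter-intersection pruning sound: supporters
of the extension are computed by checking only the new transition within
the current supporter set. By default only *maximal* sequences are
emitted (a partial that extends successfully is not separately
reported); `emit_prefixes=True` also reports extendable intermediate
lengths, covering the alternative reading of "finalized when no
extension is possible". Output is deduplicated on the code sequence and
sorted lexicographically; trajectory IDs follow that order, so the
builder is deterministic regardless of worklist processing order.

Trajectory filters reduce the output: `bc` keeps trajectories containing
a bladder-cancer-related code (C67, C77, C78, C79 at the analysis level,
or any registered treatment code), `neoplasm` keeps trajectories
touching the neoplasm chapter.

## Clustering

Trajectory-graph mode (default): nodes are trajectory IDs, edge weights
the Jaccard index of the trajectories' code sets (zero-weight edges are
dropped from storage, which MCL treats identically). Event-graph mode
reproduces the older strategy — nodes are codes, edges the consecutive
pairs observed in trajectories, weighted by a count-based Jaccard — and
assigns a trajectory only when *all* its codes land in one cluster, so
trajectories spanning code clusters stay unassigned. The trajectory
graph removes that defect by construction: assignment is total.

The MCL implementation uses scipy sparse matrices. Numerical choices,
all needed for determinism and unstated in standard presentations of the
algorithm: self-loop weight per node equals its maximum incident weight
(minimum 1e-6); expansion is a matrix square; inflation (default 2.0)
is an elementwise power followed by column renormalization; entries
below 1e-5 are pruned each iteration; convergence is a maximum entry
change below 1e-8, capped at 200 iterations (non-convergence returns the
current interpretation with a flag). Clusters are read from attractor
rows (diagonal mass above 1e-7), overlapping attractor systems are
merged, a node claimed by several clusters goes to the lowest index, and
unclaimed nodes become singletons. Cluster indices are ordered by
decreasing size, ties by smallest member, so "cluster 0" is always the
largest.

## Synthetic cohorts

The generator emulates exactly the structure the estimator assumes:
patients with sex and birth year drawn uniformly over a configured
range; an anchor diagnosis given to every patient early in a 15-year
observation window (emulating a disease-defined cohort — and exercising
the fact that an event present in everyone cannot be scored, since no
comparison group without it exists); background diagnoses as first
arrivals of constant-hazard processes, independent across codes and
patients; and planted chains whose carriers progress transition by
transition with configured penetrance and uniform gap. An `age_linked`
background code doubles as a confounder: its hazard steps up for the
older half of the birth-year range, so two such codes are crudely
associated but conditionally independent given stratum.

Defaults are a 5,000-patient cohort, ten background codes with hazards
of 2–6% per year, and three chains of three events each (penetrance
0.8/0.7/0.6, carrier fractions 15/12/10%, gap ranges 200–900 to
300–1100 days) — sized so that planted supports sit comfortably above a
`minPatients=20` floor while background co-occurrence stays informative.
The manifest lists every planted pair and chain with its analytic
expected support (carriers × penetranceᵏ) and, given an analysis window,
whether it is recoverable (every planted gap range intersects the
window).

What the generator does **not** emulate: code-frequency distributions of
real ICD data, care-pathway structure, hazard trends over calendar time
or age beyond the step confounder, censoring and mortality,
coding errors, or correlated background diagnoses. Passing tests
therefore demonstrate the correctness of the statistics under the
model's assumptions, not robustness to real-world coding noise.

## Validation design and problem sizes

The test suite checks every estimator against an independent brute-force
oracle: a crude two-cohort RR for exhaustive mode (exact equality), a
per-stratum enumeration of the sampling expectation (5% relative
tolerance at 2,000 iterations), `scipy.stats.binomtest` for the
directionality test (1e-12 over all splits with n ≤ 60), and exhaustive
sequence enumeration for the trajectory builder (set equality on
8-code, 300-patient fixtures). End-to-end properties use 20 seeds each:
type-I control on 1,000-patient null cohorts (significant fraction ≤
2α), recovery of ≥95% of recoverable planted chains with zero reversed
pairs on 5,000-patient cohorts (iterations 200, minPatients 20), and
rejection of the age-confounded pair in ≥18/20 seeds. These sizes keep
the full suite around two minutes on one CPU while leaving every
statistical check adequately powered; the acceptance script uses the
same measurements at 5–10 seeds.

## Limitations

- Matching covers sex and birth-year group only; region or other
  covariates in the source data are not part of the matching key.
- The comparison-group anchor convention (rank-matched inherited
  exposure dates) is one defensible choice among several; alternatives
  (history-start anchoring) would change comparison counts for strongly
  time-skewed codes.
- Empirical p-values are one-sided for elevated risk; protective
  associations (RR < 1) are never selected, by design.
- MCL hyperparameters are conventions (inflation 2.0); cluster
  granularity is sensitive to inflation and should be explored per data
  set.
- The event-graph clustering mode is provided for comparison and
  inherits its known defect (unassigned trajectories) deliberately.
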