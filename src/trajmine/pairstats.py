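"""Relative-risk estimation for ordered event pairs via matched sampling.

For every ordered pair of events (A, B) the question is whether patients
diagnosed with A develop B afterwards (within a bounded time window) more
often than comparable patients never diagnosed with A.  A prospective
cohort study is emulated on the retrospective data: the exposed group P1
is every patient with A, and a comparison group P2 of equal size is drawn
repeatedly from the non-exposed patients, matched on (sex, birth-year
group) strata to protect against Simpson's paradox.  The relative risk is

    RR = rate(B after A in P1) / mean over draws of rate(B in matched P2)

and the empirical p-value is the add-one estimator of how often a random
matched comparison group shows a B rate at least as high as the exposed
group.

Because a non-exposed patient has no A date, counting "B after not-A"
needs a time anchor: each sampled comparison patient inherits the
exposure date of the exposed patient it is rank-matched with inside its
stratum, and B must fall within the same [min_gap, max_gap] window after
that inherited date.

Bidirectional pairs (both orientations with RR > 1) are resolved with an
exact two-sided binomial test on which event came first among patients
carrying both; only a significantly dominant orientation survives.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from ._durations import parse_duration
from .cohort import Cohort, PatientRecord

__all__ = [
    "SamplingConfig",
    "PairStats",
    "pair_occurs",
    "prefilter_pairs",
    "sample_comparison_group",
    "estimate_rr",
    "compute_pair_stats",
    "directionality_test",
    "first_occurrence_counts",
    "select_pairs",
    "adjust_pvalues",
]

FORWARD = "forward"
REVERSE = "reverse"
BOTH_DROPPED = "both_dropped"
UNIDIRECTIONAL = "unidirectional"


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the pair-mining experiment.

    ``iterations`` is the number of matched comparison groups drawn per
    pair; ``min_gap``/``max_gap`` bound the days between the two events
    of a pair (inclusive); ``min_patients`` is both the prefilter
    threshold and the minimum exposed-with-B count for selection;
    ``alpha`` is the significance level shared by the empirical RR test
    and the directionality test.  ``correction`` is the multiple-testing
    adjustment applied across all scored pairs ("none", "bh" or
    "bonferroni").  ``exhaustive`` replaces sampling by the full
    non-exposed population in a single iteration (crude two-cohort RR,
    mainly for validation).
    """

    iterations: int = 400
    min_gap: int = parse_duration("6M")
    max_gap: int = parse_duration("5Y")
    min_patients: int = 100
    alpha: float = 0.05
    correction: str = "none"
    rng_seed: int = 0
    exhaustive: bool = False

    def __post_init__(self):
        object.__setattr__(self, "min_gap", parse_duration(self.min_gap))
        object.__setattr__(self, "max_gap", parse_duration(self.max_gap))
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 <= self.min_gap <= self.max_gap):
            raise ValueError("need 0 <= min_gap <= max_gap")
        if self.min_patients < 1:
            raise ValueError("min_patients must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("none", "bh", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class PairStats:
    """Scored ordered pair (a -> b)."""

    a: str
    b: str
    n_exposed: int  # eligible exposed patients (after stratum truncation)
    n_ab: int  # exposed patients with B after A inside the window
    rr: float
    p_value: float
    n_comparison_b_mean: float
    direction: str = UNIDIRECTIONAL
    direction_p: float = float("nan")
    shortfall: int = 0  # exposed patients dropped for lack of matched controls
    unsampleable: bool = False
    p_adjusted: float = field(default=float("nan"))


# -- elementary predicates ----------------------------------------------------


def pair_occurs(patient: PatientRecord, a: str, b: str, min_gap: int, max_gap: int) -> bool:
    """True iff the patient's first B falls [min_gap, max_gap] days after its first A."""
    da = patient.day_of(a)
    db = patient.day_of(b)
    if da is None or db is None:
        return False
    return min_gap <= db - da <= max_gap


def _pair_mask(cohort: Cohort, a: str, b: str, min_gap: int, max_gap: int) -> np.ndarray:
    da = cohort.days_of(a)
    db = cohort.days_of(b)
    diff = db - da
    with np.errstate(invalid="ignore"):
        return (diff >= min_gap) & (diff <= max_gap)


def prefilter_pairs(cohort: Cohort, config: SamplingConfig, codes: list[str] | None = None) -> list[tuple[str, str]]:
    """Ordered pairs whose raw windowed co-occurrence count meets min_patients.

    Pairs failing this cheap count can never satisfy the selection rule
    n_ab >= min_patients, so they are not worth a sampling experiment.
    """
    codes = sorted(codes) if codes is not None else cohort.codes
    out: list[tuple[str, str]] = []
    for a in codes:
        da = cohort.days_of(a)
        for b in codes:
            if a == b:
                continue
            diff = cohort.days_of(b) - da
            with np.errstate(invalid="ignore"):
                n = int(((diff >= config.min_gap) & (diff <= config.max_gap)).sum())
            if n >= config.min_patients:
                out.append((a, b))
    return out


# -- matched sampling ---------------------------------------------------------


def _code_hash(code: str) -> int:
    return int.from_bytes(hashlib.sha256(code.encode()).digest()[:4], "big")


def pair_rng(seed: int, a: str, b: str) -> np.random.Generator:
    """Per-pair random stream, independent of pair iteration order.

    Deriving the stream from (seed, a, b) makes results identical no
    matter how the pair space is chunked across workers.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2**31, _code_hash(a), _code_hash(b)])
    )


def sample_comparison_group(
    cohort: Cohort, exposed_mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw one matched comparison group for the given exposure mask.

    Per stratum, as many non-exposed patients are drawn (without
    replacement) as the stratum holds exposed patients; strata short of
    controls are truncated symmetrically.  Returns (exposed index array,
    sampled comparison index array, shortfall); the two arrays are
    rank-aligned.
    """
    exp_idx: list[np.ndarray] = []
    cmp_idx: list[np.ndarray] = []
    shortfall = 0
    for (_, _), members in sorted(cohort.stratum_members().items()):
        e = members[exposed_mask[members]]
        u = members[~exposed_mask[members]]
        k = min(e.size, u.size)
        shortfall += e.size - k
        if k == 0:
            continue
        exp_idx.append(e[:k])
        cmp_idx.append(rng.choice(u, size=k, replace=False))
    if not exp_idx:
        return np.empty(0, dtype=int), np.empty(0, dtype=int), shortfall
    return np.concatenate(exp_idx), np.concatenate(cmp_idx), shortfall


def estimate_rr(
    cohort: Cohort, a: str, b: str, config: SamplingConfig, rng: np.random.Generator | None = None
) -> PairStats:
    """Estimate the relative risk of B following A by matched sampling.

    In exhaustive mode the comparison group is the entire non-exposed
    population in one iteration (comparison B counts are unanchored code
    presence), which reduces the estimator to the crude two-cohort RR.
    """
    if rng is None:
        rng = pair_rng(config.rng_seed, a, b)
    da = cohort.days_of(a)
    db = cohort.days_of(b)
    exposed_mask = ~np.isnan(da)
    in_window = _pair_mask(cohort, a, b, config.min_gap, config.max_gap)

    if config.exhaustive:
        n1 = int(exposed_mask.sum())
        n2 = int((~exposed_mask).sum())
        if n1 == 0 or n2 == 0:
            return PairStats(a, b, n1, 0, float("nan"), 1.0, 0.0, unsampleable=True)
        n_ab = int(in_window[exposed_mask].sum())
        c = int((~np.isnan(db))[~exposed_mask].sum())
        er = n_ab / n1
        cr = c / n2
        rr = math.inf if cr == 0 else er / cr
        p = (1 + (1 if cr >= er else 0)) / 2
        return PairStats(a, b, n1, n_ab, rr, p, float(c))

    # stratum-wise exposed/unexposed splits (fixed across iterations)
    strata = []
    shortfall = 0
    for (_, _), members in sorted(cohort.stratum_members().items()):
        e = members[exposed_mask[members]]
        u = members[~exposed_mask[members]]
        k = min(e.size, u.size)
        shortfall += e.size - k
        if k > 0:
            strata.append((e[:k], u, k))
    n1 = sum(k for _, _, k in strata)
    if n1 == 0:
        return PairStats(a, b, 0, 0, float("nan"), 1.0, 0.0, shortfall=shortfall, unsampleable=True)

    exposed_used = np.concatenate([e for e, _, _ in strata])
    n_ab = int(in_window[exposed_used].sum())
    er = n_ab / n1

    iters = config.iterations
    counts = np.zeros(iters, dtype=np.int64)
    for e, u, k in strata:
        anchors = da[e]  # inherited exposure dates, rank-matched
        b_days = db[u]
        # one uniformly random k-subset (with random rank order) per iteration
        sel = rng.random((iters, u.size)).argsort(axis=1)[:, :k]
        diff = b_days[sel] - anchors[None, :]
        with np.errstate(invalid="ignore"):
            counts += ((diff >= config.min_gap) & (diff <= config.max_gap)).sum(axis=1)
    comp_rates = counts / n1
    mean_rate = float(comp_rates.mean())
    rr = math.inf if mean_rate == 0 else er / mean_rate
    p = float((1 + int((comp_rates >= er).sum())) / (iters + 1))
    return PairStats(a, b, n1, n_ab, rr, p, float(counts.mean()), shortfall=shortfall)


def compute_pair_stats(
    cohort: Cohort,
    config: SamplingConfig,
    codes: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], PairStats]:
    """Score every prefiltered ordered pair.

    Work is a flat pair list with per-pair random streams, so chunking it
    across workers cannot change any result; this sequential driver is
    the reference implementation of that contract.
    """
    if pairs is None:
        pairs = prefilter_pairs(cohort, config, codes)
    out: dict[tuple[str, str], PairStats] = {}
    for a, b in pairs:
        out[(a, b)] = estimate_rr(cohort, a, b, config)
    return out


# -- directionality -----------------------------------------------------------


def first_occurrence_counts(
    cohort: Cohort, a: str, b: str, min_gap: int, max_gap: int
) -> tuple[int, int]:
    """Windowed counts of (A first, B first) among patients with both codes."""
    n_ab = int(_pair_mask(cohort, a, b, min_gap, max_gap).sum())
    n_ba = int(_pair_mask(cohort, b, a, min_gap, max_gap).sum())
    return n_ab, n_ba


def directionality_test(n_ab_first: int, n_ba_first: int, alpha: float = 0.05) -> tuple[str, float]:
    """Exact two-sided binomial test of which orientation dominates.

    Tests ``n_ab_first`` successes out of ``n_ab_first + n_ba_first``
    trials against probability 0.5 (exact integer arithmetic).  Returns
    (direction, p): the majority direction when p < alpha, otherwise
    ``both_dropped``.  Zero trials drop both orientations with p = 1.
    """
    n = n_ab_first + n_ba_first
    if n == 0:
        return BOTH_DROPPED, 1.0
    k_hi = max(n_ab_first, n_ba_first)
    tail = sum(math.comb(n, j) for j in range(k_hi, n + 1))
    p = min(1.0, 2.0 * tail / 2**n)
    if p >= alpha or n_ab_first == n_ba_first:
        return BOTH_DROPPED, p
    return (FORWARD if n_ab_first > n_ba_first else REVERSE), p


# -- selection ----------------------------------------------------------------


def adjust_pvalues(pvalues: np.ndarray, method: str) -> np.ndarray:
    """Multiple-testing adjustment: identity, Benjamini-Hochberg, or Bonferroni."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        # enforce monotonicity from the largest rank down
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


def select_pairs(
    stats: dict[tuple[str, str], PairStats], cohort: Cohort, config: SamplingConfig
) -> list[PairStats]:
    """Pairs that enter trajectory building.

    A pair survives when RR > 1, its (corrected) empirical p-value is
    below alpha, at least ``min_patients`` exposed patients show the
    windowed A-then-B sequence, and — when the reverse orientation also
    has RR > 1 — the binomial directionality test significantly favours
    it.  Output is sorted (a, b) for determinism.
    """
    keys = sorted(stats)
    scored = [k for k in keys if not stats[k].unsampleable]
    padj = adjust_pvalues(np.array([stats[k].p_value for k in scored]), config.correction)
    for k, q in zip(scored, padj):
        stats[k].p_adjusted = float(q)

    def rr_positive(k: tuple[str, str]) -> bool:
        s = stats.get(k)
        return s is not None and not s.unsampleable and s.rr > 1.0

    selected: list[PairStats] = []
    for key in keys:
        s = stats[key]
        if s.unsampleable or not (s.rr > 1.0):
            continue
        if not (s.p_adjusted < config.alpha):
            continue
        if s.n_ab < config.min_patients:
            continue
        rev = (s.b, s.a)
        if rr_positive(rev):
            f, r = first_occurrence_counts(cohort, s.a, s.b, config.min_gap, config.max_gap)
            direction, dp = directionality_test(f, r, config.alpha)
            s.direction_p = dp
            if direction != FORWARD:
                continue
            s.direction = FORWARD
        else:
            s.direction = UNIDIRECTIONAL
        selected.append(s)
    return sorted(selected, key=lambda s: (s.a, s.b))
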