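"""Independent brute-force oracles used to check the fast implementations.

Everything here enumerates over patients or sequences directly, with no
shared code paths with the package's vectorized or worklist algorithms.
"""

from __future__ import annotations

import math
from itertools import permutations

from trajmine.cohort import Cohort


def windowed_pair_count(cohort: Cohort, a: str, b: str, min_gap: int, max_gap: int) -> int:
    """Double loop over patients: first-B minus first-A inside the window."""
    n = 0
    for p in cohort.patients:
        da = db = None
        for ev in p.events:
            if ev.code == a and da is None:
                da = ev.day
            if ev.code == b and db is None:
                db = ev.day
        if da is not None and db is not None and min_gap <= db - da <= max_gap:
            n += 1
    return n


def crude_rr(cohort: Cohort, a: str, b: str, min_gap: int, max_gap: int) -> float:
    """Two-cohort relative risk: windowed A-then-B rate among exposed over
    unanchored B rate among the non-exposed."""
    exposed = [p for p in cohort.patients if p.day_of(a) is not None]
    unexposed = [p for p in cohort.patients if p.day_of(a) is None]
    if not exposed or not unexposed:
        return float("nan")
    n_ab = sum(
        1 for p in exposed
        if p.day_of(b) is not None and min_gap <= p.day_of(b) - p.day_of(a) <= max_gap
    )
    n_b = sum(1 for p in unexposed if p.day_of(b) is not None)
    er = n_ab / len(exposed)
    cr = n_b / len(unexposed)
    return math.inf if cr == 0 else er / cr


def stratified_expected_rr(cohort: Cohort, a: str, b: str, min_gap: int, max_gap: int) -> float:
    """Closed-form expectation of the matched-sampling RR estimator.

    Enumerates every stratum exactly: the expected comparison count per
    rank-matched anchor is the mean windowed-B indicator over ALL
    non-exposed patients of the stratum, because each sample position is
    marginally uniform over them.
    """
    n1 = 0
    n_ab = 0
    expected_c = 0.0
    for (_, _), members in sorted(cohort.stratum_members().items()):
        exposed = [i for i in members if cohort.patients[i].day_of(a) is not None]
        unexposed = [i for i in members if cohort.patients[i].day_of(a) is None]
        k = min(len(exposed), len(unexposed))
        if k == 0:
            continue
        kept = exposed[:k]
        n1 += k
        for i in kept:
            p = cohort.patients[i]
            db = p.day_of(b)
            if db is not None and min_gap <= db - p.day_of(a) <= max_gap:
                n_ab += 1
            anchor = p.day_of(a)
            hits = 0
            for j in unexposed:
                dbu = cohort.patients[j].day_of(b)
                if dbu is not None and min_gap <= dbu - anchor <= max_gap:
                    hits += 1
            expected_c += hits / len(unexposed)
    if n1 == 0:
        return float("nan")
    er = n_ab / n1
    cr = expected_c / n1
    return math.inf if cr == 0 else er / cr


def enumerate_trajectories(cohort: Cohort, selected_pairs, min_len, max_len, min_patients,
                           min_gap, max_gap, emit_prefixes=False):
    """Exhaustive trajectory enumeration over all code sequences.

    Generates every sequence of distinct codes whose consecutive pairs
    are all selected and whose exact supporter count meets the floor,
    then keeps sequences in [min_len, max_len] that cannot be extended
    (or every such sequence when ``emit_prefixes``).
    """
    pair_set = {(p.a, p.b) for p in selected_pairs}
    codes = sorted({c for ab in pair_set for c in ab})

    def support(seq):
        n = 0
        for p in cohort.patients:
            days = [p.day_of(c) for c in seq]
            if any(d is None for d in days):
                continue
            if all(min_gap <= y - x <= max_gap and y > x for x, y in zip(days, days[1:])):
                n += 1
        return n

    valid = set()
    for length in range(2, max_len + 1):
        for seq in permutations(codes, length):
            if all((x, y) in pair_set for x, y in zip(seq, seq[1:])) and support(seq) >= min_patients:
                valid.add(seq)

    out = set()
    for seq in valid:
        if len(seq) < min_len:
            continue
        extendable = len(seq) < max_len and any(
            seq + (z,) in valid for z in codes if z not in seq
        )
        if emit_prefixes or not extendable:
            out.add(seq)
    return out
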