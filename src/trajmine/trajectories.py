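"""Chaining selected event pairs into patient-supported trajectories.

A trajectory is an ordered sequence of distinct event codes where every
consecutive pair was selected by the relative-risk stage and enough
patients actually follow the full sequence: a patient supports a
trajectory when the first occurrences of its codes appear in order with
every consecutive gap inside [min_gap, max_gap] days.

Construction is a worklist algorithm: selected pairs seed partial
trajectories, each partial extends with every selected pair that
overlaps its last code (copying, since one partial can extend several
ways), and a partial is finalized when no extension keeps enough
supporters or the length cap is reached.  Support is anti-monotone under
extension, which both prunes the search and guarantees every prefix of a
valid trajectory was reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._durations import parse_duration
from .cohort import Cohort
from .pairstats import PairStats
from .vocab import Vocabulary, normalize_code

__all__ = [
    "Trajectory",
    "TrajectoryConfig",
    "support_count",
    "build_trajectories",
    "apply_trajectory_filters",
    "BC_FILTER_DIAGNOSES",
]

# bladder-cancer-related diagnosis codes for the "bc" trajectory filter
BC_FILTER_DIAGNOSES = ("C67", "C77", "C78", "C79")


@dataclass(frozen=True)
class TrajectoryConfig:
    min_len: int = 3
    max_len: int = 5
    min_patients: int = 100
    min_gap: int = parse_duration("6M")
    max_gap: int = parse_duration("5Y")
    filters: tuple[str, ...] = ()
    emit_prefixes: bool = False  # also emit extendable intermediate lengths

    def __post_init__(self):
        object.__setattr__(self, "min_gap", parse_duration(self.min_gap))
        object.__setattr__(self, "max_gap", parse_duration(self.max_gap))
        if not (2 <= self.min_len <= self.max_len):
            raise ValueError("need 2 <= min_len <= max_len")
        if self.min_patients < 1:
            raise ValueError("min_patients must be >= 1")


@dataclass
class Trajectory:
    tid: int
    codes: tuple[str, ...]
    support: int
    supporters: frozenset[str]
    transition_rr: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.codes)


def support_count(
    cohort: Cohort, codes: tuple[str, ...] | list[str], min_gap: int, max_gap: int
) -> tuple[int, frozenset[str]]:
    """Exact supporter count and set for a code sequence.

    A patient supports the sequence iff every consecutive first-occurrence
    gap lies in [min_gap, max_gap] days (dates strictly increasing follows
    whenever min_gap >= 1; a zero min_gap still requires non-decreasing
    order with the window bound).
    """
    if len(codes) < 2:
        raise ValueError("a trajectory has at least 2 codes")
    if len(set(codes)) != len(codes):
        raise ValueError("trajectory codes must be distinct")
    days = [cohort.days_of(c) for c in codes]
    ok = np.ones(len(cohort), dtype=bool)
    for prev, nxt in zip(days, days[1:]):
        diff = nxt - prev
        with np.errstate(invalid="ignore"):
            ok &= (diff >= min_gap) & (diff <= max_gap) & (diff > 0)
    idx = np.flatnonzero(ok)
    return int(idx.size), frozenset(cohort.patients[i].pid for i in idx)


def build_trajectories(
    selected_pairs: list[PairStats], cohort: Cohort, config: TrajectoryConfig
) -> list[Trajectory]:
    """Worklist construction of all finalized trajectories.

    Every selected pair with enough supporters is a partial trajectory;
    a partial [.., Y] extends with every selected pair (Y, Z) whose code Z
    it does not contain yet, provided the extended sequence keeps at
    least ``min_patients`` supporters.  By default only finalized
    (non-extendable or maximal-length) sequences of length >= min_len are
    emitted; ``emit_prefixes`` additionally emits every extendable
    intermediate sequence.  Output is deduplicated on the code sequence
    and sorted lexicographically; trajectory ids follow that order.
    """
    rr_of = {(p.a, p.b): p.rr for p in selected_pairs}
    by_head: dict[str, list[str]] = {}
    for p in selected_pairs:
        by_head.setdefault(p.a, []).append(p.b)
    for v in by_head.values():
        v.sort()

    results: dict[tuple[str, ...], tuple[int, frozenset[str]]] = {}
    # seed with selected pairs that themselves have enough supporters
    work: list[tuple[tuple[str, ...], frozenset[str]]] = []
    for p in sorted(selected_pairs, key=lambda s: (s.a, s.b)):
        n, supp = support_count(cohort, (p.a, p.b), config.min_gap, config.max_gap)
        if n >= config.min_patients:
            work.append(((p.a, p.b), supp))

    while work:
        codes, supp = work.pop()
        extended = False
        if len(codes) < config.max_len:
            with_last = cohort.days_of(codes[-1])
            for z in by_head.get(codes[-1], ()):
                if z in codes:
                    continue
                # sound pruning: supporters of codes+z follow codes and carry z
                cand = codes + (z,)
                n, s = _extend_support(cohort, supp, with_last, z, config)
                assert n <= len(supp), "support must be anti-monotone under extension"
                if n >= config.min_patients:
                    extended = True
                    work.append((cand, s))
        if (not extended or config.emit_prefixes) and len(codes) >= config.min_len:
            results[codes] = (len(supp), supp)

    out: list[Trajectory] = []
    for tid, codes in enumerate(sorted(results)):
        n, supp = results[codes]
        out.append(
            Trajectory(
                tid=tid,
                codes=codes,
                support=n,
                supporters=supp,
                transition_rr=tuple(rr_of[(x, y)] for x, y in zip(codes, codes[1:])),
            )
        )
    return out


def _extend_support(
    cohort: Cohort,
    supporters: frozenset[str],
    last_days: np.ndarray,
    z: str,
    config: TrajectoryConfig,
) -> tuple[int, frozenset[str]]:
    """Supporters of an extended sequence, restricted to current supporters.

    Only the new transition needs checking: a patient supporting the
    prefix supports the extension iff its first Z falls inside the window
    after the prefix's last code.
    """
    z_days = cohort.days_of(z)
    diff = z_days - last_days
    with np.errstate(invalid="ignore"):
        ok = (diff >= config.min_gap) & (diff <= config.max_gap) & (diff > 0)
    idx = np.flatnonzero(ok)
    new = frozenset(cohort.patients[i].pid for i in idx) & supporters
    return len(new), new


def apply_trajectory_filters(
    trajectories: list[Trajectory],
    filters: list[str] | tuple[str, ...],
    vocab: Vocabulary,
    level: int | None = None,
    extra_bc_codes: tuple[str, ...] = (),
) -> list[Trajectory]:
    """Keep trajectories containing at least one code from each named filter set.

    ``bc`` matches the bladder-cancer-related diagnoses (C67, C77, C78,
    C79, mapped to the vocabulary's analysis level or CCSR categories)
    plus any registered bladder-cancer treatment codes; ``neoplasm``
    matches any code whose chapter is the neoplasm chapter (chapter II in
    WHO numbering).  An empty filter list is the identity.
    """
    if not filters:
        return list(trajectories)
    sets = [_filter_codeset(name, vocab, level, extra_bc_codes) for name in filters]
    out = []
    for t in trajectories:
        codes = set(t.codes)
        if all(_matches(codes, s, vocab) for s in sets):
            out.append(t)
    return out


def _filter_codeset(
    name: str, vocab: Vocabulary, level: int | None, extra_bc_codes: tuple[str, ...]
) -> set[str] | str:
    if name == "bc":
        codes = set()
        for c in BC_FILTER_DIAGNOSES + tuple(extra_bc_codes):
            mapped = vocab.map_to_level(c, level) if level is not None else normalize_code(c)
            codes.add(mapped if mapped is not None else normalize_code(c))
        codes.update(c for c in vocab.codes if vocab.is_treatment(c))
        return codes
    if name == "neoplasm":
        return "neoplasm"  # sentinel: membership via chapter walk
    raise ValueError(f"unknown trajectory filter {name!r}; registered: ['bc', 'neoplasm']")


def _matches(codes: set[str], codeset: set[str] | str, vocab: Vocabulary) -> bool:
    if codeset == "neoplasm":
        for c in codes:
            if c in vocab.codes and vocab.ancestry(c)[-1] == "II":
                return True
        return False
    return bool(codes & codeset)
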