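"""Patient cohorts: table ingestion, history normalization, strata, filters.

A cohort is the unit the pair-mining statistics run on.  Event histories
are normalized before any counting: codes are aggregated to the analysis
level of the vocabulary, excluded codes are dropped, and only the FIRST
dated occurrence of each (patient, level-mapped code) is retained —
diagnoses are treated as one-time onset events, so repeat billing codes
never inflate pair counts.

Matched sampling needs strata: patients are partitioned on (sex,
birth-year group), the birth-year range being split into equal-width
bins.  Dates are held internally as proleptic-Gregorian ordinal day
numbers so that all gap arithmetic is integer day math.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import Vocabulary, normalize_code

__all__ = [
    "PatientRecord",
    "EventOccurrence",
    "Cohort",
    "CohortError",
    "read_patient_table",
    "read_event_table",
    "assign_age_groups",
    "apply_patient_filters",
    "DEFAULT_ANCHOR_CODES",
]

# cohort-defining diagnoses: bladder cancer and its personal-history codes
DEFAULT_ANCHOR_CODES = ("C67", "188", "Z85.51", "V10.52")

SEX_UNKNOWN, SEX_MALE, SEX_FEMALE = 0, 1, 2
_SEX_TOKENS = {"M": SEX_MALE, "MALE": SEX_MALE, "1": SEX_MALE,
               "F": SEX_FEMALE, "FEMALE": SEX_FEMALE, "2": SEX_FEMALE}
_SEX_NAMES = {SEX_UNKNOWN: "unknown", SEX_MALE: "male", SEX_FEMALE: "female"}

# fraction of unparseable event rows tolerated before the load is aborted
MAX_DROP_FRACTION = 0.10


class CohortError(ValueError):
    """Raised for malformed cohort inputs or impossible configurations."""


@dataclass(frozen=True)
class EventOccurrence:
    code: str
    day: int  # proleptic-Gregorian ordinal

    @property
    def date(self) -> _dt.date:
        return _dt.date.fromordinal(self.day)


@dataclass
class PatientRecord:
    pid: str
    sex: int = SEX_UNKNOWN
    birth_year: int | None = None
    tags: frozenset[str] = frozenset()
    events: list[EventOccurrence] = field(default_factory=list)
    anchor_day: int | None = None

    @property
    def sex_name(self) -> str:
        return _SEX_NAMES[self.sex]

    @property
    def anchor_date(self) -> _dt.date | None:
        return None if self.anchor_day is None else _dt.date.fromordinal(self.anchor_day)

    def age_at_anchor(self) -> int | None:
        """Whole-year age at the anchor event by calendar-year subtraction.

        De-identified extracts carry only a birth year, so age is anchor
        year minus birth year.
        """
        if self.anchor_day is None or self.birth_year is None:
            return None
        return _dt.date.fromordinal(self.anchor_day).year - self.birth_year

    def day_of(self, code: str) -> int | None:
        for ev in self.events:
            if ev.code == code:
                return ev.day
        return None


class Cohort:
    """Normalized patient population with stratum and code indexes.

    Construction from tables goes through :func:`read_patient_table` and
    :func:`read_event_table`; direct construction from
    :class:`PatientRecord` objects is supported for synthetic data and
    tests.
    """

    def __init__(self, patients: list[PatientRecord], n_age_groups: int | None = None):
        self.patients: list[PatientRecord] = patients
        self.pid_index: dict[str, int] = {p.pid: i for i, p in enumerate(patients)}
        if len(self.pid_index) != len(patients):
            raise CohortError("duplicate patient identifiers in cohort")
        self.n_age_groups: int | None = None
        self._rebuild_arrays()
        if n_age_groups is not None:
            assign_age_groups(self, n_age_groups)

    # -- indexes --------------------------------------------------------------

    def _rebuild_arrays(self) -> None:
        n = len(self.patients)
        self.sex = np.array([p.sex for p in self.patients], dtype=np.int8)
        self.birth_year = np.array(
            [p.birth_year if p.birth_year is not None else -1 for p in self.patients],
            dtype=np.int32,
        )
        self.anchor_day = np.array(
            [p.anchor_day if p.anchor_day is not None else -1 for p in self.patients],
            dtype=np.int64,
        )
        code_days: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.patients):
            for ev in p.events:
                arr = code_days.get(ev.code)
                if arr is None:
                    arr = np.full(n, np.nan)
                    code_days[ev.code] = arr
                arr[i] = ev.day
        self.code_days = code_days
        self.age_bin = np.full(n, -1, dtype=np.int32)
        self.stratum_id = np.full(n, -1, dtype=np.int32)
        self._strata: dict[tuple[int, int], np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def codes(self) -> list[str]:
        return sorted(self.code_days)

    @property
    def code_index(self) -> dict[str, set[str]]:
        """code -> set of patient ids having that code (normalized history)."""
        out: dict[str, set[str]] = {}
        for code, days in self.code_days.items():
            idx = np.flatnonzero(~np.isnan(days))
            out[code] = {self.patients[i].pid for i in idx}
        return out

    @property
    def strata(self) -> dict[tuple[str, int], set[str]]:
        """(sex name, age group) -> patient-id set, over stratifiable patients."""
        out: dict[tuple[str, int], set[str]] = {}
        for (sex, bin_), idx in self._strata.items():
            out[(_SEX_NAMES[sex], bin_)] = {self.patients[i].pid for i in idx}
        return out

    def stratum_members(self) -> dict[tuple[int, int], np.ndarray]:
        """Raw stratum index arrays keyed by (sex code, age bin)."""
        return self._strata

    def days_of(self, code: str) -> np.ndarray:
        """Per-patient first-occurrence day of ``code`` (NaN where absent)."""
        arr = self.code_days.get(code)
        if arr is None:
            return np.full(len(self.patients), np.nan)
        return arr

    def subset(self, keep: np.ndarray) -> "Cohort":
        """Sub-cohort of the patients selected by boolean mask ``keep``."""
        kept = [p for p, k in zip(self.patients, keep) if k]
        sub = Cohort(kept)
        if self.n_age_groups is not None:
            assign_age_groups(sub, self.n_age_groups)
        return sub


# -- table readers ------------------------------------------------------------


def _read_csv(source, **kw) -> pd.DataFrame:
    return pd.read_csv(source, dtype=str, skipinitialspace=True, **kw)


def read_patient_table(source, delimiter: str = ",") -> list[PatientRecord]:
    """Read the patient-information CSV: PID, SEX, BIRTH_YEAR[, TAGS].

    SEX accepts the case-insensitive tokens F/M/FEMALE/MALE and the
    numeric 1 (male) / 2 (female) dialect.  TAGS is a semicolon-separated
    label list (disease stage or treatment-group tags).  Rows with an
    unparseable birth year are skipped with a warning and counted; an
    empty birth-year field is accepted as unknown.  Duplicate patient
    identifiers are an error.
    """
    df = _read_csv(source, sep=delimiter)
    cols = {c.strip().upper(): c for c in df.columns}
    for req in ("PID", "SEX", "BIRTH_YEAR"):
        if req not in cols:
            raise CohortError(f"patient table missing column {req}; got {list(df.columns)}")
    out: list[PatientRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    for _, row in df.iterrows():
        pid = str(row[cols["PID"]]).strip()
        if pid in seen:
            raise CohortError(f"duplicate patient identifier {pid!r}")
        seen.add(pid)
        sex = _SEX_TOKENS.get(str(row[cols["SEX"]]).strip().upper(), SEX_UNKNOWN)
        by_raw = row[cols["BIRTH_YEAR"]]
        by_str = "" if by_raw is None or (isinstance(by_raw, float) and np.isnan(by_raw)) else str(by_raw).strip()
        if by_str in ("", "nan"):
            birth_year: int | None = None
        else:
            try:
                birth_year = int(by_str)
            except (ValueError, TypeError):
                n_skipped += 1
                continue
        tags: frozenset[str] = frozenset()
        if "TAGS" in cols and isinstance(row[cols["TAGS"]], str):
            tags = frozenset(t.strip() for t in row[cols["TAGS"]].split(";") if t.strip())
        out.append(PatientRecord(pid=pid, sex=sex, birth_year=birth_year, tags=tags))
    if n_skipped:
        warnings.warn(f"{n_skipped} patient rows skipped: unparseable birth year", stacklevel=2)
    return out


def read_event_table(
    source,
    vocab: Vocabulary,
    level: int,
    patients: list[PatientRecord],
    anchor_codes: tuple[str, ...] = DEFAULT_ANCHOR_CODES,
    delimiter: str = ",",
) -> Cohort:
    """Read the timestamped event CSV (PID, CODE, DATE) into a cohort.

    Events are level-mapped through ``vocab``, excluded codes dropped,
    per-patient per-code first occurrences retained and histories date
    sorted.  Anchor dates are taken from the RAW (pre-normalization)
    history: the earliest date of any configured anchor code.  Rows with
    unknown patient ids or unparseable dates are dropped and counted;
    more than 10% dropped rows aborts the load as a data-quality guard.
    """
    df = _read_csv(source, sep=delimiter)
    cols = {c.strip().upper(): c for c in df.columns}
    for req in ("PID", "CODE", "DATE"):
        if req not in cols:
            raise CohortError(f"event table missing column {req}; got {list(df.columns)}")
    n_rows = len(df)
    pid_index = {p.pid: i for i, p in enumerate(patients)}
    dates = pd.to_datetime(df[cols["DATE"]], errors="coerce", format="ISO8601")
    bad_date = dates.isna()
    pids = df[cols["PID"]].astype(str).str.strip()
    unknown_pid = ~pids.isin(pid_index.keys())
    dropped = int((bad_date | unknown_pid).sum())
    if n_rows > 0 and dropped / n_rows > MAX_DROP_FRACTION:
        raise CohortError(
            f"{dropped}/{n_rows} event rows dropped (bad dates or unknown patients); "
            "more than 10% suggests a malformed extract"
        )
    ok = ~(bad_date | unknown_pid)
    anchors = {normalize_code(c) for c in anchor_codes}
    raw_events: dict[int, dict[str, int]] = {}
    anchor_day: dict[int, int] = {}
    for pid, code, ts in zip(pids[ok], df[cols["CODE"]][ok], dates[ok]):
        i = pid_index[pid]
        raw = normalize_code(str(code))
        day = ts.date().toordinal()
        if raw in anchors and day < anchor_day.get(i, 10**9):
            anchor_day[i] = day
        mapped = vocab.map_to_level(raw, level)
        if mapped is None or vocab.is_excluded(mapped) or vocab.is_excluded(raw):
            continue
        per = raw_events.setdefault(i, {})
        if day < per.get(mapped, 10**9):
            per[mapped] = day
    for i, p in enumerate(patients):
        per = raw_events.get(i, {})
        p.events = sorted(
            (EventOccurrence(code=c, day=d) for c, d in per.items()),
            key=lambda e: (e.day, e.code),
        )
        p.anchor_day = anchor_day.get(i)
    cohort = Cohort(patients)
    cohort.dropped_event_rows = dropped  # type: ignore[attr-defined]
    return cohort


# -- strata and filters -------------------------------------------------------


def assign_age_groups(cohort: Cohort, n_age_groups: int) -> Cohort:
    """Partition patients into (sex, birth-year bin) strata.

    The observed birth-year range [min, max] is split into
    ``n_age_groups`` equal-width bins; patients on the upper boundary are
    clamped into the last bin.  Patients with unknown sex or birth year
    are left unstratified (stratum id -1) and never enter matched
    sampling.
    """
    if n_age_groups < 1:
        raise CohortError("n_age_groups must be >= 1")
    if len(cohort) == 0:  # filtering may legitimately empty a cohort
        cohort.n_age_groups = n_age_groups
        cohort._strata = {}
        return cohort
    known = cohort.birth_year >= 0
    if not known.any():
        raise CohortError("no patient has a known birth year")
    lo = int(cohort.birth_year[known].min())
    hi = int(cohort.birth_year[known].max())
    width = (hi - lo + 1) / n_age_groups
    bins = np.full(len(cohort.patients), -1, dtype=np.int32)
    bins[known] = np.minimum(
        ((cohort.birth_year[known] - lo) / width).astype(np.int32), n_age_groups - 1
    )
    cohort.age_bin = bins
    cohort.n_age_groups = n_age_groups
    stratifiable = known & (cohort.sex != SEX_UNKNOWN)
    stratum = np.full(len(cohort.patients), -1, dtype=np.int32)
    strata: dict[tuple[int, int], np.ndarray] = {}
    sid = 0
    for sex in (SEX_MALE, SEX_FEMALE):
        for b in range(n_age_groups):
            mask = stratifiable & (cohort.sex == sex) & (bins == b)
            idx = np.flatnonzero(mask)
            if idx.size:
                strata[(sex, b)] = idx
                stratum[idx] = sid
                sid += 1
    cohort.stratum_id = stratum
    cohort._strata = strata
    return cohort


def _age_filter(threshold: int, at_least: bool):
    def pred(p: PatientRecord) -> bool:
        age = p.age_at_anchor()
        if age is None:
            return False
        return age >= threshold if at_least else age < threshold
    return pred


PATIENT_FILTERS = {
    "male": lambda p: p.sex == SEX_MALE,
    "female": lambda p: p.sex == SEX_FEMALE,
    "age70+": _age_filter(70, at_least=True),
    "age70-": _age_filter(70, at_least=False),
    "NMIBC": lambda p: "NMIBC" in p.tags,
    "MIBC": lambda p: "MIBC" in p.tags,
    "mUC": lambda p: "mUC" in p.tags,
}


def apply_patient_filters(cohort: Cohort, filters: list[str]) -> Cohort:
    """Sub-cohort of patients satisfying ALL named filters.

    ``age70+`` / ``age70-`` compare whole-year age at the anchor event;
    stage filters test tag membership; ``tag:X`` tests an arbitrary tag.
    Strata and indexes are rebuilt on the sub-cohort.
    """
    preds = []
    for name in filters:
        if name in PATIENT_FILTERS:
            preds.append(PATIENT_FILTERS[name])
        elif name.startswith("tag:"):
            tag = name[4:]
            preds.append(lambda p, tag=tag: tag in p.tags)
        else:
            raise CohortError(
                f"unknown patient filter {name!r}; registered: {sorted(PATIENT_FILTERS)} or tag:<label>"
            )
    if not preds:
        return cohort
    keep = np.array([all(pred(p) for pred in preds) for p in cohort.patients], dtype=bool)
    return cohort.subset(keep)
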