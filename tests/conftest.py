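"""Shared fixtures: a miniature ICD-style hierarchy and hand-built cohorts."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from trajmine.cohort import Cohort, EventOccurrence, PatientRecord, assign_age_groups

# chapter II (neoplasms) with a bladder-cancer branch, a respiratory branch,
# the pregnancy chapter XV and the Z-code chapter XXI
HIERARCHY_TSV = """code\tparent\tdepth\tname
II\t\t0\tNeoplasms
C64-C68\tII\t1\tMalignant neoplasms of urinary tract
C67\tC64-C68\t2\tMalignant neoplasm of bladder
C67.2\tC67\t3\tMalignant neoplasm of lateral wall of bladder
C67.9\tC67\t3\tMalignant neoplasm of bladder, unspecified
C77\tC64-C68\t2\tSecondary malignant neoplasm of lymph nodes
X\t\t0\tDiseases of the respiratory system
J40-J47\tX\t1\tChronic lower respiratory diseases
J44\tJ40-J47\t2\tOther chronic obstructive pulmonary disease
XIV\t\t0\tDiseases of the genitourinary system
N30-N39\tXIV\t1\tOther diseases of the urinary system
N39\tN30-N39\t2\tOther disorders of urinary system
IX\t\t0\tDiseases of the circulatory system
I10-I16\tIX\t1\tHypertensive diseases
I10\tI10-I16\t2\tEssential hypertension
XV\t\t0\tPregnancy, childbirth and the puerperium
O10\tXV\t1\tPre-existing hypertension complicating pregnancy
XXI\t\t0\tFactors influencing health status
Z85\tXXI\t1\tPersonal history of malignant neoplasm
Z85.51\tZ85\t2\tPersonal history of malignant neoplasm of bladder
"""

HIERARCHY_XML = """<?xml version="1.0" encoding="UTF-8"?>
<ClaML>
  <Class code="II" kind="chapter"><Rubric><Label>Neoplasms</Label></Rubric></Class>
  <Class code="C64-C68" kind="block"><SuperClass code="II"/><Rubric><Label>Malignant neoplasms of urinary tract</Label></Rubric></Class>
  <Class code="C67" kind="category"><SuperClass code="C64-C68"/><Rubric><Label>Malignant neoplasm of bladder</Label></Rubric></Class>
  <Class code="C67.2" kind="subcategory"><SuperClass code="C67"/><Rubric><Label>Lateral wall of bladder</Label></Rubric></Class>
</ClaML>
"""


@pytest.fixture
def hierarchy_tsv(tmp_path):
    p = tmp_path / "hierarchy.tsv"
    p.write_text(HIERARCHY_TSV)
    return p


@pytest.fixture
def hierarchy_xml(tmp_path):
    p = tmp_path / "hierarchy.xml"
    p.write_text(HIERARCHY_XML)
    return p


@pytest.fixture
def vocab(hierarchy_tsv):
    from trajmine.vocab import load_icd_hierarchy

    return load_icd_hierarchy(hierarchy_tsv)


DAY0 = dt.date(2010, 1, 1).toordinal()


def make_patient(pid, events, sex=1, birth_year=1950, anchor_day=None, tags=()):
    """events: iterable of (code, day offset from DAY0)."""
    return PatientRecord(
        pid=pid,
        sex=sex,
        birth_year=birth_year,
        tags=frozenset(tags),
        events=sorted(
            (EventOccurrence(code=c, day=DAY0 + d) for c, d in events),
            key=lambda e: (e.day, e.code),
        ),
        anchor_day=None if anchor_day is None else DAY0 + anchor_day,
    )


def make_cohort(specs, n_age_groups=2):
    """specs: list of (pid, sex, birth_year, [(code, day), ...])."""
    patients = [make_patient(pid, evs, sex=sex, birth_year=by) for pid, sex, by, evs in specs]
    cohort = Cohort(patients)
    assign_age_groups(cohort, n_age_groups)
    return cohort


def random_cohort(rng: np.random.Generator, n_patients=100, codes=("A", "B", "C", "D"),
                  p_code=0.5, max_day=2000, n_age_groups=2):
    """Random histories: each patient carries each code independently at a uniform day."""
    specs = []
    for i in range(n_patients):
        evs = [(c, int(rng.integers(0, max_day))) for c in codes if rng.random() < p_code]
        specs.append((f"P{i:04d}", 1 + int(rng.integers(0, 2)), 1930 + int(rng.integers(0, 60)), evs))
    return make_cohort(specs, n_age_groups=n_age_groups)
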