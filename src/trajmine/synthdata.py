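"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the statistical structure the pair-mining stage
assumes: a population with demographic strata, independent background
diagnoses arriving at constant per-year hazards, and planted causal
chains A -> B -> C in which carriers progress from one event to the next
with a configured penetrance and a uniformly distributed gap.  Every
patient also carries the cohort anchor diagnosis (mirroring a
disease-defined cohort where the anchor itself can never be scored,
because no comparison group without it exists).

An optional age-linked hazard multiplier creates confounded code pairs
whose crude relative risk exceeds 1 while the age/sex-stratified risk is
about 1 — the scenario matched sampling must reject.

The generator emits the exact CSV dialects the cohort reader consumes, a
flat hierarchy table for the vocabulary loader, and a JSON manifest of
every planted pair and chain with analytic expected supports.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PlantedChain", "BackgroundCode", "SimConfig", "generate_cohort", "expected_truth"]

_EPOCH = _dt.date(2000, 1, 1).toordinal()


@dataclass(frozen=True)
class PlantedChain:
    """A planted causal chain: carriers progress through ``codes`` in order."""

    codes: tuple[str, ...]
    penetrance: float = 0.8  # per-transition progression probability
    gap_days: tuple[int, int] = (200, 900)  # uniform per-transition gap range
    carrier_fraction: float = 0.15

    def __post_init__(self):
        if not (0 < self.penetrance <= 1):
            raise ValueError("penetrance must be in (0, 1]")
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in [0, 1]")
        if len(self.codes) < 2:
            raise ValueError("a chain needs at least 2 codes")


@dataclass(frozen=True)
class BackgroundCode:
    """Independent background diagnosis with a constant per-year hazard.

    ``age_linked`` makes the hazard generational: patients born before
    the midpoint of the birth-year range see ``age_slope``-fold the base
    hazard.  Two such codes form a confounded pair — crudely associated
    through the shared age effect but conditionally independent — which
    age/sex-stratified matching must reject.
    """

    code: str
    hazard_per_year: float = 0.05
    age_linked: bool = False
    age_slope: float = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a mid-sized registry extract: 5,000 patients,
    balanced sexes, birth years 1930-1990, a 15-year observation window,
    ~10 background diagnoses with per-year hazards of a few percent, and
    three planted chains of three events each.
    """

    n_patients: int = 5000
    sex_ratio: float = 0.5  # fraction male
    birth_year_range: tuple[int, int] = (1930, 1990)
    observation_years: int = 15
    background_codes: tuple[BackgroundCode, ...] = tuple(
        BackgroundCode(code=f"B{i:02d}", hazard_per_year=h)
        for i, h in enumerate([0.02, 0.03, 0.04, 0.05, 0.06, 0.02, 0.03, 0.04, 0.05, 0.06])
    )
    chains: tuple[PlantedChain, ...] = (
        PlantedChain(codes=("K00", "K01", "K02"), penetrance=0.8, gap_days=(200, 900), carrier_fraction=0.15),
        PlantedChain(codes=("L00", "L01", "L02"), penetrance=0.7, gap_days=(250, 1000), carrier_fraction=0.12),
        PlantedChain(codes=("M00", "M01", "M02"), penetrance=0.6, gap_days=(300, 1100), carrier_fraction=0.10),
    )
    anchor_code: str = "C67"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.background_codes and not self.chains:
            raise ValueError("config defines no event codes at all")
        for bc in self.background_codes:
            if bc.hazard_per_year < 0:
                raise ValueError("hazards must be >= 0")


def _age_factor(cfg: SimConfig, birth_year: np.ndarray, bc: BackgroundCode) -> np.ndarray:
    if not bc.age_linked:
        return np.ones_like(birth_year, dtype=float)
    lo, hi = cfg.birth_year_range
    midpoint = (lo + hi + 1) // 2
    return np.where(birth_year < midpoint, bc.age_slope, 1.0)


def generate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic cohort.

    Returns (patient table, event table, manifest); when ``out_dir`` is
    given, additionally writes ``patients.csv``, ``events.csv``,
    ``hierarchy.tsv`` and ``manifest.json`` there.  Everything is
    deterministic under ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed % 2**31)
    n = config.n_patients
    window_days = config.observation_years * 365

    pids = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.sex_ratio, "M", "F")
    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=n)

    rows: list[tuple[str, str, int]] = []  # (pid, code, day offset)

    # anchor: everyone, early in the window
    anchor_day = rng.integers(0, max(window_days // 10, 1), size=n)
    for i in range(n):
        rows.append((pids[i], config.anchor_code, int(anchor_day[i])))

    # background codes: first arrival of a constant-hazard process
    for bc in config.background_codes:
        rate = bc.hazard_per_year * _age_factor(config, birth_year, bc)
        with np.errstate(divide="ignore"):
            wait = rng.exponential(np.where(rate > 0, 1.0 / np.maximum(rate, 1e-300), np.inf))
        days = wait * 365.0
        hit = (rate > 0) & (days < window_days)
        for i in np.flatnonzero(hit):
            rows.append((pids[i], bc.code, int(days[i])))

    # planted chains
    for chain in config.chains:
        carriers = np.flatnonzero(rng.random(n) < chain.carrier_fraction)
        max_total = (len(chain.codes) - 1) * chain.gap_days[1]
        start_cap = max(window_days - max_total, 1)
        starts = rng.integers(0, start_cap, size=carriers.size)
        for idx, i in enumerate(carriers):
            day = int(starts[idx])
            rows.append((pids[i], chain.codes[0], day))
            for nxt in chain.codes[1:]:
                if rng.random() >= chain.penetrance:
                    break
                day += int(rng.integers(chain.gap_days[0], chain.gap_days[1] + 1))
                if day >= window_days:
                    break
                rows.append((pids[i], nxt, day))

    patients = pd.DataFrame({"PID": pids, "SEX": sex, "BIRTH_YEAR": birth_year, "TAGS": ""})
    events = pd.DataFrame(rows, columns=["PID", "CODE", "_day"])
    events["DATE"] = [
        _dt.date.fromordinal(_EPOCH + d).isoformat() for d in events["_day"]
    ]
    events = events.drop(columns="_day").sort_values(["PID", "DATE", "CODE"], kind="stable")
    events = events.reset_index(drop=True)

    manifest = expected_truth(config)
    manifest["realized"] = {
        "n_patients": int(n),
        "n_event_rows": int(len(events)),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        patients.to_csv(out / "patients.csv", index=False)
        events.to_csv(out / "events.csv", index=False)
        (out / "hierarchy.tsv").write_text(hierarchy_tsv(config))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return patients, events, manifest


def hierarchy_tsv(config: SimConfig) -> str:
    """Flat hierarchy table covering every synthetic code.

    Codes are placed at depth 2 under a single synthetic chapter/block so
    that an analysis at level 2 uses them unchanged.
    """
    lines = ["code\tparent\tdepth\tname", "SYN\t\t0\tSynthetic chapter", "SYN0\tSYN\t1\tSynthetic block"]
    codes = {config.anchor_code}
    codes.update(bc.code for bc in config.background_codes)
    for chain in config.chains:
        codes.update(chain.codes)
    for c in sorted(codes):
        lines.append(f"{c}\tSYN0\t2\t{c} (synthetic)")
    return "\n".join(lines) + "\n"


def expected_truth(
    config: SimConfig, min_gap: int | None = None, max_gap: int | None = None
) -> dict:
    """Ground-truth manifest: planted pairs/chains with analytic expectations.

    Expected pair support for transition j of a chain is
    ``n_patients * carrier_fraction * penetrance**j`` (gap truncation at
    the window end is ignored; the generator reserves room for the full
    chain, so truncation is rare).  When an analysis gap window is given,
    each pair and chain is marked recoverable iff every planted gap range
    intersects [min_gap, max_gap].
    """
    pairs = []
    chains = []
    for chain in config.chains:
        n_carriers = config.n_patients * chain.carrier_fraction
        chain_rec = True
        for j, (a, b) in enumerate(zip(chain.codes, chain.codes[1:]), start=1):
            rec = _gap_recoverable(chain.gap_days, min_gap, max_gap)
            chain_rec &= rec
            pairs.append(
                {
                    "a": a,
                    "b": b,
                    "expected_support": n_carriers * chain.penetrance**j,
                    "expected_rr_sign": ">1",
                    "recoverable": rec,
                }
            )
        chains.append(
            {
                "codes": list(chain.codes),
                "expected_support": n_carriers * chain.penetrance ** (len(chain.codes) - 1),
                "recoverable": chain_rec,
            }
        )
    return {
        "config": _config_dict(config),
        "planted_pairs": pairs,
        "planted_chains": chains,
        "anchor_code": config.anchor_code,
    }


def _gap_recoverable(gap_days: tuple[int, int], min_gap: int | None, max_gap: int | None) -> bool:
    if min_gap is None or max_gap is None:
        return True
    return gap_days[0] <= max_gap and gap_days[1] >= min_gap


def _config_dict(config: SimConfig) -> dict:
    return asdict(config)  # nested dataclasses become plain dicts
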