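"""Result writers and the end-to-end pipeline driver.

A run produces, under one output folder: a ``.tab`` table of selected
pairs with their relative risks, a ``.tab`` table of trajectories, a
``clusters/`` folder with per-cluster GML graphs in two annotation modes
(edge labels = patients following the trajectory up to that transition,
or = the transition's relative risk), cluster CSVs linking patients,
trajectories and clusters, a per-cluster summary, a machine-readable run
log with the stage counts, and the serialized run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._durations import parse_duration
from . import cohort as cohort_mod
from .clustering import (
    ClusterSet,
    TRAJECTORY_MODE,
    UNASSIGNED,
    cluster_trajectories,
)
from .cohort import Cohort, apply_patient_filters, assign_age_groups, read_event_table, read_patient_table
from .pairstats import PairStats, SamplingConfig, compute_pair_stats, select_pairs
from .trajectories import Trajectory, TrajectoryConfig, apply_trajectory_filters, build_trajectories, support_count
from .vocab import Vocabulary, load_ccsr_map, load_default_exclusions, load_icd_hierarchy

__all__ = [
    "RunConfig",
    "PipelineError",
    "write_pairs_tab",
    "read_pairs_tab",
    "write_trajectories_tab",
    "read_trajectories_tab",
    "write_cluster_gml",
    "write_cluster_csvs",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Every parameter of an end-to-end run (serialized for provenance)."""

    patient_file: str
    vocab_file: str
    event_file: str
    out_dir: str
    nof_age_groups: int = 10
    min_patients: int = 100
    max_gap: str | int = "5Y"
    min_gap: str | int = "6M"
    min_trajectory_length: int = 3
    max_trajectory_length: int = 5
    iterations: int = 400
    level: int = 2
    pfilters: tuple[str, ...] = ()
    tfilters: tuple[str, ...] = ()
    alpha: float = 0.05
    correction: str = "none"
    inflation: float = 2.0
    seed: int = 0
    emit_prefixes: bool = False
    cluster_mode: str = TRAJECTORY_MODE
    exhaustive_sampling: bool = False
    anchor_codes: tuple[str, ...] = cohort_mod.DEFAULT_ANCHOR_CODES
    delimiter: str = ","


# -- tab tables ----------------------------------------------------------------

_PAIR_COLS = ["A_CODE", "A_NAME", "B_CODE", "B_NAME", "N_EXPOSED", "N_AB", "RR", "P", "DIRECTION_P"]


def write_pairs_tab(pairs: list[PairStats], vocab: Vocabulary, path: str | Path) -> Path:
    """Selected pairs as a tab-separated table (stable (a, b) row order)."""
    path = Path(path)
    rows = []
    for p in sorted(pairs, key=lambda s: (s.a, s.b)):
        rows.append(
            [p.a, vocab.name_of(p.a), p.b, vocab.name_of(p.b),
             p.n_exposed, p.n_ab, repr(p.rr), repr(p.p_value), repr(p.direction_p)]
        )
    df = pd.DataFrame(rows, columns=_PAIR_COLS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_pairs_tab(path: str | Path) -> list[PairStats]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            PairStats(
                a=str(r["A_CODE"]), b=str(r["B_CODE"]),
                n_exposed=int(r["N_EXPOSED"]), n_ab=int(r["N_AB"]),
                rr=float(r["RR"]), p_value=float(r["P"]),
                n_comparison_b_mean=float("nan"), direction_p=float(r["DIRECTION_P"]),
            )
        )
    return out


def write_trajectories_tab(
    trajectories: list[Trajectory], vocab: Vocabulary, path: str | Path, max_len: int | None = None
) -> Path:
    """Trajectory table with code/name/RR columns padded to the longest trajectory."""
    path = Path(path)
    k = max_len or (max((len(t) for t in trajectories), default=2))
    cols = (["TID", "LENGTH", "SUPPORT"]
            + [f"CODE_{i+1}" for i in range(k)]
            + [f"NAME_{i+1}" for i in range(k)]
            + [f"RR_{i+1}" for i in range(k - 1)])
    rows = []
    for t in trajectories:
        pad = k - len(t)
        rows.append(
            [t.tid, len(t), t.support]
            + list(t.codes) + [""] * pad
            + [vocab.name_of(c) for c in t.codes] + [""] * pad
            + [repr(r) for r in t.transition_rr] + [""] * (k - 1 - len(t.transition_rr))
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_trajectories_tab(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    k = sum(1 for c in df.columns if c.startswith("CODE_"))
    out = []
    for _, r in df.iterrows():
        codes = tuple(str(r[f"CODE_{i+1}"]) for i in range(k) if str(r[f"CODE_{i+1}"]))
        rrs = tuple(float(r[f"RR_{i+1}"]) for i in range(len(codes) - 1))
        out.append(
            Trajectory(
                tid=int(r["TID"]), codes=codes, support=int(r["SUPPORT"]),
                supporters=frozenset(), transition_rr=rrs,
            )
        )
    return out


# -- GML -----------------------------------------------------------------------


def _gml_quote(s: str) -> str:
    return '"' + str(s).replace("\\", "\\\\").replace('"', "'") + '"'


def write_cluster_gml(
    clusterset: ClusterSet,
    trajectories: list[Trajectory],
    pairs: list[PairStats],
    mode: str,
    out_dir: str | Path,
    vocab: Vocabulary | None = None,
    cohort: Cohort | None = None,
    min_gap: int | None = None,
    max_gap: int | None = None,
) -> list[Path]:
    """One GML file per cluster, annotated per ``mode``.

    ``patients`` mode keeps one directed edge per member trajectory per
    transition, labeled with the number of patients following that
    trajectory up to and including the transition (prefix support,
    computed from the cohort when available, otherwise the trajectory's
    full support).  ``rr`` mode merges parallel edges per code pair and
    labels them with the pair's relative risk.
    """
    if mode not in ("patients", "rr"):
        raise ValueError(f"unknown GML annotation mode {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rr_of = {(p.a, p.b): p.rr for p in pairs}
    by_tid = {t.tid: t for t in trajectories}
    written: list[Path] = []
    by_cluster: dict[int, list[Trajectory]] = {}
    for tid, ci in sorted(clusterset.assignment.items()):
        if ci == UNASSIGNED:
            continue
        by_cluster.setdefault(ci, []).append(by_tid[tid])
    for ci, members in sorted(by_cluster.items()):
        codes = sorted({c for t in members for c in t.codes})
        node_id = {c: i for i, c in enumerate(codes)}
        lines = ["graph ["]
        if mode == "patients":
            lines.append("  multigraph 1")
        lines.append("  directed 1")
        for c in codes:
            name = vocab.name_of(c) if vocab is not None else c
            lines.append(f"  node [ id {node_id[c]} label {_gml_quote(name)} ]")
        if mode == "patients":
            for t in members:
                for j, (x, y) in enumerate(zip(t.codes, t.codes[1:])):
                    lbl = _prefix_support(t, j, cohort, min_gap, max_gap)
                    lines.append(
                        f"  edge [ source {node_id[x]} target {node_id[y]} "
                        f"label {_gml_quote(lbl)} key {_gml_quote(f't{t.tid}e{j}')} ]"
                    )
        else:
            seen: set[tuple[str, str]] = set()
            for t in members:
                for x, y in zip(t.codes, t.codes[1:]):
                    if (x, y) in seen:
                        continue
                    seen.add((x, y))
                    rr = rr_of.get((x, y), float("nan"))
                    lines.append(
                        f"  edge [ source {node_id[x]} target {node_id[y]} label {_gml_quote(f'{rr:.2f}')} ]"
                    )
        lines.append("]")
        path = out_dir / f"cluster_{ci}_{mode}.gml"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written


def _prefix_support(
    t: Trajectory, j: int, cohort: Cohort | None, min_gap: int | None, max_gap: int | None
) -> int:
    if cohort is None or min_gap is None or max_gap is None:
        return t.support
    n, _ = support_count(cohort, t.codes[: j + 2], min_gap, max_gap)
    return n


# -- cluster CSVs ---------------------------------------------------------------


def write_cluster_csvs(
    clusterset: ClusterSet,
    trajectories: list[Trajectory],
    cohort: Cohort,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Cluster info, patient-cluster membership, and per-cluster summary CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    info_rows = []
    patient_rows = []
    for t in sorted(trajectories, key=lambda t: t.tid):
        ci = clusterset.assignment.get(t.tid, UNASSIGNED)
        info_rows.append([t.tid, ci, t.support, ">".join(t.codes)])
        for pid in sorted(t.supporters):
            p = cohort.patients[cohort.pid_index[pid]]
            patient_rows.append([pid, t.tid, ci, p.sex_name, p.age_at_anchor()])
    info = pd.DataFrame(info_rows, columns=["TID", "CLUSTER", "SUPPORT", "CODES"])
    members = pd.DataFrame(patient_rows, columns=["PID", "TID", "CLUSTER", "SEX", "AGE_AT_ANCHOR"])
    summary_rows = []
    for ci in sorted(c for c in members["CLUSTER"].unique() if c != UNASSIGNED):
        sub = members[members["CLUSTER"] == ci]
        distinct = sub.drop_duplicates("PID")
        pct_female = 100.0 * (distinct["SEX"] == "female").mean() if len(distinct) else 0.0
        mean_age = distinct["AGE_AT_ANCHOR"].dropna().mean()
        summary_rows.append(
            [ci, int((info["CLUSTER"] == ci).sum()), len(distinct), round(pct_female, 4),
             round(float(mean_age), 4) if pd.notna(mean_age) else ""]
        )
    summary = pd.DataFrame(
        summary_rows, columns=["CLUSTER", "N_TRAJECTORIES", "N_PATIENTS", "PCT_FEMALE", "MEAN_AGE_AT_ANCHOR"]
    )
    paths = {
        "cluster_info": out_dir / "cluster_info.csv",
        "patient_clusters": out_dir / "patient_clusters.csv",
        "cluster_summary": out_dir / "cluster_summary.csv",
    }
    info.to_csv(paths["cluster_info"], index=False)
    members.to_csv(paths["patient_clusters"], index=False)
    summary.to_csv(paths["cluster_summary"], index=False)
    return paths


# -- pipeline ------------------------------------------------------------------


def _load_vocabulary(path: str | Path) -> Vocabulary:
    """Sniff the vocabulary dialect: CCSR CSV vs ICD hierarchy (XML/TSV)."""
    head = Path(path).read_text(encoding="utf-8", errors="replace")[:4096].upper()
    if "ICD10" in head.split("\n", 1)[0] and "CCSR" in head.split("\n", 1)[0]:
        return load_ccsr_map(path)
    return load_icd_hierarchy(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write every artifact.

    Returns the run log dict.  Any stage failure raises
    :class:`PipelineError` naming the stage, after removing the partial
    outputs written so far.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    stage = "setup"
    t_start = time.perf_counter()

    def _log(msg: str) -> None:
        print(f"[trajmine +{time.perf_counter() - t_start:7.2f}s] {msg}", file=sys.stderr)

    try:
        stage = "vocabulary"
        vocab = _load_vocabulary(config.vocab_file)
        excluded, whitelist = load_default_exclusions()
        vocab.configure_exclusions(
            excluded & set(vocab.codes), whitelist | {c for c in config.anchor_codes}
        )
        _log(f"vocabulary: {len(vocab)} codes ({vocab.mode})")

        stage = "cohort"
        patients = read_patient_table(config.patient_file, delimiter=config.delimiter)
        cohort = read_event_table(
            config.event_file, vocab, config.level, patients,
            anchor_codes=config.anchor_codes, delimiter=config.delimiter,
        )
        assign_age_groups(cohort, config.nof_age_groups)
        if config.pfilters:
            cohort = apply_patient_filters(cohort, list(config.pfilters))
        _log(f"cohort: {len(cohort)} patients, {len(cohort.codes)} distinct codes")

        stage = "pair statistics"
        min_gap = parse_duration(config.min_gap)
        max_gap = parse_duration(config.max_gap)
        scfg = SamplingConfig(
            iterations=config.iterations, min_gap=min_gap, max_gap=max_gap,
            min_patients=config.min_patients, alpha=config.alpha,
            correction=config.correction, rng_seed=config.seed,
            exhaustive=config.exhaustive_sampling,
        )
        stats = compute_pair_stats(cohort, scfg)
        selected = select_pairs(stats, cohort, scfg)
        _log(f"pairs: {len(stats)} tested, {len(selected)} selected")
        created.append(write_pairs_tab(selected, vocab, out_dir / "pairs.tab"))

        stage = "trajectories"
        tcfg = TrajectoryConfig(
            min_len=config.min_trajectory_length, max_len=config.max_trajectory_length,
            min_patients=config.min_patients, min_gap=min_gap, max_gap=max_gap,
            filters=tuple(config.tfilters), emit_prefixes=config.emit_prefixes,
        )
        trajs = build_trajectories(selected, cohort, tcfg)
        trajs = apply_trajectory_filters(trajs, list(config.tfilters), vocab, level=config.level)
        _log(f"trajectories: {len(trajs)}")
        created.append(
            write_trajectories_tab(trajs, vocab, out_dir / "trajectories.tab", max_len=tcfg.max_len)
        )

        stage = "clustering"
        n_clusters = 0
        n_unassigned = 0
        if trajs:
            cs = cluster_trajectories(trajs, mode=config.cluster_mode, inflation=config.inflation)
            n_clusters = len([c for c in cs.clusters if c])
            n_unassigned = len(cs.unassigned)
            cluster_dir = out_dir / "clusters"
            created += write_cluster_gml(
                cs, trajs, selected, "patients", cluster_dir, vocab=vocab,
                cohort=cohort, min_gap=min_gap, max_gap=max_gap,
            )
            created += write_cluster_gml(cs, trajs, selected, "rr", cluster_dir, vocab=vocab)
            created += list(write_cluster_csvs(cs, trajs, cohort, cluster_dir).values())
        _log(f"clusters: {n_clusters} ({n_unassigned} unassigned)")

        stage = "run log"
        log = {
            "n_patients": len(cohort),
            "n_codes": len(cohort.codes),
            "dropped_event_rows": getattr(cohort, "dropped_event_rows", 0),
            "pairs_tested": len(stats),
            "pairs_selected": len(selected),
            "n_trajectories": len(trajs),
            "n_clusters": n_clusters,
            "n_unassigned": n_unassigned,
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        (out_dir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, default=str) + "\n"
        )
        return log
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
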