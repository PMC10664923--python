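"""Medical event vocabularies: ICD-10 hierarchy, CCSR categories, treatments.

A :class:`Vocabulary` holds the universe of event codes an analysis runs
over, with enough hierarchy information to (a) aggregate codes to a chosen
analysis level and (b) exclude whole chapters (e.g. pregnancy-related
codes) from pair mining.

Two input dialects are supported for ICD-style hierarchies: a ClaML-like
XML file (``Class`` elements with a code, a ``SuperClass`` reference and a
preferred label) and a flat tab-separated table ``code<TAB>parent<TAB>
depth<TAB>name``.  CCSR category tables (CSV) define a flat two-level
vocabulary in which every ICD-10 code maps to exactly one clinical
category.

Treatment codes (conventionally prefixed ``TX:``) sit outside any
hierarchy: they are their own analysis-level code at every level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from lxml import etree

__all__ = [
    "EventCode",
    "Vocabulary",
    "load_icd_hierarchy",
    "load_ccsr_map",
    "load_default_exclusions",
    "VocabularyError",
]

TREATMENT_PREFIX = "TX:"

_MAX_DEPTH = 6  # parent chains longer than this indicate a cycle/corruption


class VocabularyError(ValueError):
    """Raised for malformed or inconsistent vocabulary inputs."""


def normalize_code(code: str) -> str:
    """Canonical code form: uppercase, no dots, no surrounding whitespace.

    Treatment codes keep their ``TX:`` prefix but are normalized the same
    way after the prefix.
    """
    code = code.strip()
    if code.upper().startswith(TREATMENT_PREFIX):
        return TREATMENT_PREFIX + code[len(TREATMENT_PREFIX):].strip().replace(".", "").upper()
    return code.replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class EventCode:
    """One node of the event-code universe."""

    code: str
    name: str = ""
    depth: int = 0
    parent: str | None = None
    kind: str = "diagnosis"  # "diagnosis" | "treatment"


@dataclass
class Vocabulary:
    """Event-code universe with hierarchy ancestry and exclusion flags.

    Parameters
    ----------
    codes
        Mapping from normalized code to :class:`EventCode`.
    mode
        ``"icd-hierarchy"`` (codes aggregate to an ancestor at the
        analysis depth) or ``"ccsr"`` (codes map through a category
        table).
    """

    codes: dict[str, EventCode] = field(default_factory=dict)
    mode: str = "icd-hierarchy"
    excluded: set[str] = field(default_factory=set)
    whitelist: set[str] = field(default_factory=set)
    ccsr_of: dict[str, str] = field(default_factory=dict)
    unknown_policy: str = "drop"  # "drop" (with warning counter) | "error"
    # bookkeeping for codes seen at use time that the vocabulary cannot place
    unmapped_codes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        for code, ec in self.codes.items():
            if ec.parent is not None and ec.parent not in self.codes:
                raise VocabularyError(
                    f"orphan code {code!r}: parent {ec.parent!r} not in vocabulary"
                )
        # no cycles / bounded chains
        for code in self.codes:
            self.ancestry(code)

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    # -- queries --------------------------------------------------------------

    def ancestry(self, code: str) -> list[str]:
        """Codes from ``code`` up to its root, inclusive."""
        code = normalize_code(code)
        chain = [code]
        cur = self.codes[code]
        while cur.parent is not None:
            if len(chain) > _MAX_DEPTH:
                raise VocabularyError(f"parent chain of {code!r} exceeds {_MAX_DEPTH} steps")
            chain.append(cur.parent)
            cur = self.codes[cur.parent]
        return chain

    def name_of(self, code: str) -> str:
        code = normalize_code(code)
        ec = self.codes.get(code)
        return ec.name if ec is not None and ec.name else code

    def is_treatment(self, code: str) -> bool:
        return normalize_code(code).startswith(TREATMENT_PREFIX)

    def map_to_level(self, code: str, level: int) -> str | None:
        """Return the ancestor of ``code`` at depth ``level``.

        Codes already at or above the requested depth are returned
        unchanged; treatment codes bypass the hierarchy entirely.  In CCSR
        mode the category of the code is returned regardless of ``level``.
        Unknown codes follow ``unknown_policy``: ``None`` is returned and
        a counter incremented (drop), or :class:`VocabularyError` raised.
        """
        if level < 0:
            raise ValueError("level must be >= 0")
        raw = normalize_code(code)
        if raw.startswith(TREATMENT_PREFIX):
            return raw
        if self.mode == "ccsr":
            cat = self.ccsr_of.get(raw)
            if cat is None:
                return self._unknown(raw)
            return cat
        ec = self.codes.get(raw)
        if ec is None:
            return self._unknown(raw)
        if ec.depth <= level:
            return raw
        chain = self.ancestry(raw)
        for anc in chain:
            if self.codes[anc].depth == level:
                return anc
        # hierarchy with gaps: fall back to the shallowest ancestor
        return chain[-1]

    def _unknown(self, code: str) -> str | None:
        if self.unknown_policy == "error":
            raise VocabularyError(f"unknown event code {code!r}")
        self.unmapped_codes[code] = self.unmapped_codes.get(code, 0) + 1
        return None

    def is_excluded(self, code: str) -> bool:
        """True iff ``code`` or any ancestor is excluded.

        Whitelisted codes take precedence over any chapter-level
        exclusion (so an anchor diagnosis inside an excluded chapter can
        still participate).
        """
        code = normalize_code(code)
        if code in self.whitelist:
            return False
        if code.startswith(TREATMENT_PREFIX):
            return False
        if code not in self.codes:
            return code in self.excluded
        return any(anc in self.excluded for anc in self.ancestry(code))

    def configure_exclusions(self, excluded: Iterable[str], whitelist: Iterable[str] = ()) -> None:
        self.excluded = {normalize_code(c) for c in excluded}
        self.whitelist = {normalize_code(c) for c in whitelist}

    def add_treatment(self, code: str, name: str = "", level: int = 0) -> None:
        """Register a treatment code as an ordinary analysis-level event."""
        code = normalize_code(code)
        if not code.startswith(TREATMENT_PREFIX):
            code = TREATMENT_PREFIX + code
        self.codes[code] = EventCode(code=code, name=name or code, depth=level, parent=None, kind="treatment")


# -- loaders ------------------------------------------------------------------


def load_icd_hierarchy(source: str | Path) -> Vocabulary:
    """Load an ICD-style hierarchy from XML (ClaML-like) or flat TSV.

    The dialect is sniffed from the file content: files starting with
    ``<`` are parsed as XML, anything else as the tab-separated
    ``code, parent, depth, name`` table (a header line is permitted).
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise VocabularyError(f"empty hierarchy file: {path}")
    if text.lstrip().startswith("<"):
        return _load_claml(text, path)
    return _load_flat_tsv(text, path)


def _load_claml(text: str, path: Path) -> Vocabulary:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message passthrough
        raise VocabularyError(f"malformed hierarchy XML {path}: {exc}") from exc
    parents: dict[str, str | None] = {}
    names: dict[str, str] = {}
    for cls in root.iter("Class"):
        code = cls.get("code")
        if code is None:
            raise VocabularyError(f"{path}: Class element without a code attribute")
        code = normalize_code(code)
        sup = cls.find("SuperClass")
        parents[code] = normalize_code(sup.get("code")) if sup is not None and sup.get("code") else None
        label = cls.find("Rubric/Label")
        if label is None:
            label = cls.find("Label")
        names[code] = "".join(label.itertext()).strip() if label is not None else code
    if not parents:
        raise VocabularyError(f"{path}: no Class records found")
    # depths by walking parent chains
    codes: dict[str, EventCode] = {}
    for code, parent in parents.items():
        depth, cur, seen = 0, parent, {code}
        while cur is not None:
            if cur not in parents:
                raise VocabularyError(f"{path}: code {code!r} references missing parent {cur!r}")
            if cur in seen or depth > _MAX_DEPTH:
                raise VocabularyError(f"{path}: cycle in parent chain of {code!r}")
            seen.add(cur)
            depth += 1
            cur = parents[cur]
        codes[code] = EventCode(code=code, name=names[code], depth=depth, parent=parent)
    return Vocabulary(codes=codes, mode="icd-hierarchy")


def _load_flat_tsv(text: str, path: Path) -> Vocabulary:
    codes: dict[str, EventCode] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    start = 1 if lines and lines[0].lower().startswith("code\t") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise VocabularyError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
        code, parent, depth_s, name = parts[0], parts[1], parts[2], parts[3]
        code = normalize_code(code)
        parent_n = normalize_code(parent) if parent.strip() else None
        try:
            depth = int(depth_s)
        except ValueError as exc:
            raise VocabularyError(f"{path}:{lineno}: bad depth {depth_s!r}") from exc
        if code in codes:
            raise VocabularyError(f"{path}:{lineno}: duplicate code {code!r}")
        codes[code] = EventCode(code=code, name=name.strip(), depth=depth, parent=parent_n)
    if not codes:
        raise VocabularyError(f"empty hierarchy file: {path}")
    return Vocabulary(codes=codes, mode="icd-hierarchy")


def load_ccsr_map(source: str | Path) -> Vocabulary:
    """Load a CCSR category table: CSV with ICD10, CCSR_CATEGORY, CCSR_DESCRIPTION.

    The resulting vocabulary's analysis-level codes are the CCSR
    categories; every ICD-10 code must map to exactly one category
    (conflicting duplicate rows are a validation error).
    """
    df = pd.read_csv(source, dtype=str)
    cols = {c.strip().upper(): c for c in df.columns}
    try:
        icd_col = cols["ICD10"]
        cat_col = cols["CCSR_CATEGORY"]
        desc_col = cols["CCSR_DESCRIPTION"]
    except KeyError as exc:
        raise VocabularyError(
            f"CCSR table must have columns ICD10, CCSR_CATEGORY, CCSR_DESCRIPTION; got {list(df.columns)}"
        ) from exc
    ccsr_of: dict[str, str] = {}
    conflicts: list[str] = []
    codes: dict[str, EventCode] = {}
    for _, row in df.iterrows():
        icd = normalize_code(str(row[icd_col]))
        cat = normalize_code(str(row[cat_col]))
        desc = str(row[desc_col]).strip()
        prev = ccsr_of.get(icd)
        if prev is not None and prev != cat:
            conflicts.append(f"{icd}: {prev} vs {cat}")
            continue
        ccsr_of[icd] = cat
        if cat not in codes:
            codes[cat] = EventCode(code=cat, name=desc, depth=0, parent=None)
        if icd not in codes:
            codes[icd] = EventCode(code=icd, name=icd, depth=1, parent=cat)
    if conflicts:
        raise VocabularyError("conflicting CCSR mappings: " + "; ".join(conflicts))
    if not ccsr_of:
        raise VocabularyError(f"empty CCSR table: {source}")
    return Vocabulary(codes=codes, mode="ccsr", ccsr_of=ccsr_of)


def load_default_exclusions() -> tuple[set[str], set[str]]:
    """Default chapter exclusions shipped with the package.

    Covers the WHO chapters for pregnancy/childbirth, perinatal
    conditions, external causes of morbidity, and factors influencing
    health status (Z codes), with the bladder-cancer history code kept as
    a whitelisted anchor.  Returns ``(excluded, whitelist)``.
    """
    data = resources.files("trajmine").joinpath("data/default_exclusions.json").read_text()
    obj = json.loads(data)
    return ({normalize_code(c) for c in obj["excluded"]},
            {normalize_code(c) for c in obj["whitelist"]})


def apply_crosswalk(codes: Mapping[str, str], crosswalk: Mapping[str, str]) -> dict[str, str]:
    """Map ICD-9 codes through an ICD-9 to ICD-10 crosswalk table.

    Codes absent from the crosswalk are kept as-is (they remain distinct
    opaque codes in the analysis).
    """
    return {normalize_code(k): normalize_code(crosswalk.get(k, v)) for k, v in codes.items()}
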