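"""Adverse-drug-effect phenotyping from diagnosis records and self-reports.

A configurable list of ICD10 codes defines which diagnoses count as possible
adverse drug effects (ADEs).  Codes whose ICD10 title carries no explicit
drug link (e.g. unspecified myositis) only count when the record's
``physician_confirmed`` flag is set -- the electronic analogue of a manual
chart review.  Every self-reported reaction counts.  Each code belongs to
one of 12 diagnostic groups defined by the leading pathophysiological
mechanism and affected organ system; group membership drives the
phenotype-refinement stage of replication.

Matching is prefix-based at the precision given in the list: a configured
``M60`` matches recorded ``M60.9``, while a configured ``M60.9`` matches
only that subcode.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclass(frozen=True)
class AdeCodeList:
    """ICD10 ADE code list with confirmation requirements and 12-group map."""

    codes: frozenset[str]
    requires_confirmation: frozenset[str]
    group_map: dict[str, str]

    def __post_init__(self) -> None:
        if not self.requires_confirmation <= self.codes:
            extra = sorted(self.requires_confirmation - self.codes)
            raise ValueError(f"requires_confirmation codes not in list: {extra}")
        unmapped = sorted(self.codes - self.group_map.keys())
        if unmapped:
            raise ValueError(f"codes without a diagnostic group: {unmapped}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_map.values()))

    def codes_in_group(self, group: str) -> set[str]:
        out = {c for c, g in self.group_map.items() if g == group}
        if not out:
            raise KeyError(f"unknown diagnostic group {group!r}")
        return out

    def match(self, icd10: str) -> str | None:
        """Longest configured code that prefix-matches ``icd10`` (dot-insensitive)."""
        bare = icd10.replace(".", "")
        best = None
        for code in self.codes:
            cb = code.replace(".", "")
            if bare.startswith(cb) and (best is None or len(cb) > len(best.replace(".", ""))):
                best = code
        return best


def load_ade_codes(path: str | Path | None = None) -> AdeCodeList:
    """Load an ADE code config (YAML); defaults to the bundled example list."""
    if path is None:
        text = (resources.files("pharmscan") / "data" / "ade_codes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    group_map: dict[str, str] = {}
    for group, codes in raw["groups"].items():
        for code in codes:
            if code in group_map:
                raise ValueError(f"code {code} assigned to two groups")
            group_map[code] = group
    return AdeCodeList(
        codes=frozenset(group_map),
        requires_confirmation=frozenset(raw.get("requires_confirmation", [])),
        group_map=group_map,
    )


@dataclass
class AdeEvent:
    code: str
    group: str
    date: object
    source: str  # "ehr" | "self_report"


@dataclass
class AdePhenotype:
    person_id: str
    events: list[AdeEvent] = field(default_factory=list)

    @property
    def is_case(self) -> bool:
        return bool(self.events)


@dataclass
class PhenotypeResult:
    phenotypes: list[AdePhenotype]
    n_skipped: int  # malformed ICD10 records dropped

    def frame(self) -> pd.DataFrame:
        """Tidy per-person table: person_id, is_case, n_events, groups."""
        rows = [{
            "person_id": p.person_id,
            "is_case": p.is_case,
            "n_events": len(p.events),
            "groups": ";".join(sorted({e.group for e in p.events})),
        } for p in self.phenotypes]
        return pd.DataFrame(rows, columns=["person_id", "is_case", "n_events", "groups"])

    def events_frame(self) -> pd.DataFrame:
        rows = [{"person_id": p.person_id, "icd10": e.code, "group": e.group,
                 "date": e.date, "source": e.source}
                for p in self.phenotypes for e in p.events]
        return pd.DataFrame(rows, columns=["person_id", "icd10", "group", "date", "source"])

    @property
    def cases(self) -> set[str]:
        return {p.person_id for p in self.phenotypes if p.is_case}


def extract_ades(
    diagnoses: pd.DataFrame,
    self_reports: pd.DataFrame | None,
    codelist: AdeCodeList,
    persons: list[str] | None = None,
) -> PhenotypeResult:
    """Derive one ADE phenotype per person.

    A diagnosis record becomes an ADE event iff its ICD10 code prefix-matches
    the configured list and either the matched code needs no confirmation or
    the record is physician-confirmed.  All self-reports become events.
    ``persons`` optionally fixes the roster (persons without events are
    emitted as non-cases); by default the roster is the union of person ids
    seen in the input tables.
    """
    events: dict[str, list[AdeEvent]] = {}
    n_skipped = 0
    for rec in diagnoses.itertuples(index=False):
        code = str(rec.icd10).strip()
        if not ICD10_RE.match(code):
            n_skipped += 1
            continue
        matched = codelist.match(code)
        if matched is None:
            continue
        if matched in codelist.requires_confirmation and not bool(rec.physician_confirmed):
            continue
        events.setdefault(str(rec.person_id), []).append(
            AdeEvent(code, codelist.group_map[matched], getattr(rec, "date", None), "ehr"))
    if n_skipped:
        logger.warning("skipped %d diagnosis records with malformed ICD10 codes",
                       n_skipped)
    if self_reports is not None:
        for rec in self_reports.itertuples(index=False):
            events.setdefault(str(rec.person_id), []).append(
                AdeEvent("self_report", "self_report", getattr(rec, "date", None),
                         "self_report"))
    roster = list(persons) if persons is not None else sorted(
        set(events)
        | set(diagnoses["person_id"].astype(str))
        | (set(self_reports["person_id"].astype(str)) if self_reports is not None else set())
    )
    phenos = [AdePhenotype(pid, sorted(events.get(pid, []),
                                       key=lambda e: (str(e.date), e.code)))
              for pid in roster]
    return PhenotypeResult(phenos, n_skipped)


def group_ades(result: PhenotypeResult, codelist: AdeCodeList) -> dict[str, set[str]]:
    """Per-person set of diagnostic groups (empty for non-cases).

    Self-reported events carry no ICD10 code and map to the pseudo-group
    ``self_report``; EHR events with a code outside the group map raise.
    """
    valid = set(codelist.group_map.values()) | {"self_report"}
    out: dict[str, set[str]] = {}
    for p in result.phenotypes:
        groups = {e.group for e in p.events}
        bad = groups - valid
        if bad:
            raise ValueError(f"events with unmapped groups for {p.person_id}: {sorted(bad)}")
        out[p.person_id] = groups
    return out
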