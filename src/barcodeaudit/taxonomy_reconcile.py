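"""Reconcile specimen species names against a fixed taxonomic checklist.

A reference library needs every name tied to one nomenclatural baseline.
Names that fail an exact checklist match are classified into the categories
that routinely surface during library construction: published synonyms,
species described after the checklist, spelling or gender-agreement slips,
and genuinely new (tentative) records.  Unidentified specimens — an empty
species field — form their own class.

Resolution order for a non-empty name:

1. exact match of the normalized binomial against the checklist;
2. lookup in the local synonym table (synonym / spelling / post-checklist);
3. fuzzy spelling match, restricted to the same genus: epithet within
   Levenshtein distance 2, or a Latin gender-suffix swap (-us/-a/-um,
   -is/-e) on an otherwise identical stem;
4. otherwise TENTATIVE_NEW.

Same-epithet/different-genus cases (changes of generic combination) are not
auto-resolved — they stay TENTATIVE_NEW with a hint in the evidence field,
since merging congeners automatically is how libraries acquire silent
misidentifications.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import edlib

from .bold_io import ChecklistTaxon, Dataset, SynonymEntry, SynonymKind

MAX_EDIT_DISTANCE = 2

#: Latin gender suffix groups treated as interchangeable on an exact stem.
_GENDER_GROUPS = (("us", "a", "um"), ("is", "e"))

#: Epithet placeholders that mean "not identified to species".
_PLACEHOLDER_EPITHETS = {"sp", "spp", "cf", "nr", "aff", "indet"}

_PAREN_RE = re.compile(r"\([^)]*\)")


class ResolutionStatus(str, Enum):
    MATCHED = "MATCHED"
    SYNONYM = "SYNONYM"
    SPELLING_VARIANT = "SPELLING_VARIANT"
    POST_CHECKLIST = "POST_CHECKLIST"
    TENTATIVE_NEW = "TENTATIVE_NEW"
    UNIDENTIFIED = "UNIDENTIFIED"


#: Statuses whose accepted_name is guaranteed to exist in the checklist.
CHECKLIST_ANCHORED = frozenset(
    {ResolutionStatus.MATCHED, ResolutionStatus.SYNONYM, ResolutionStatus.SPELLING_VARIANT}
)


@dataclass(frozen=True)
class NameResolution:
    input_name: str
    status: ResolutionStatus
    accepted_name: str = ""
    evidence: str = ""


def normalize_name(raw: str) -> str:
    """Normalize a scientific name to a bare binomial.

    Trims and collapses whitespace, removes subgenus parentheticals and
    author/year strings, capitalizes the genus and lowercases the epithet.
    Trinomials are truncated to the binomial (subspecies are not
    distinguished here).  A genus-only name, or a placeholder epithet like
    "sp.", yields just the capitalized genus.
    """
    text = _PAREN_RE.sub(" ", raw)
    tokens = text.split()
    if not tokens:
        return ""
    genus = tokens[0].capitalize()
    epithet = ""
    # the first alphabetic token after the genus is the epithet, even when
    # wrongly capitalized (case-agreement errors are a target of this step);
    # years and punctuation fragments are skipped, everything after the
    # epithet (authors, subspecies) is dropped
    for tok in tokens[1:]:
        tok = tok.strip(".,")
        if not tok or not tok.isalpha():
            continue
        epithet = tok.lower()
        break
    if not epithet or epithet in _PLACEHOLDER_EPITHETS:
        return genus
    return f"{genus} {epithet}"


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _gender_swap(a: str, b: str) -> bool:
    """True when the two epithets differ only by a gender suffix swap."""
    if a == b:
        return False
    for group in _GENDER_GROUPS:
        for sa in group:
            for sb in group:
                if sa != sb and a.endswith(sa) and b.endswith(sb):
                    if a[: -len(sa)] == b[: -len(sb)]:
                        return True
    return False


class ChecklistIndex:
    """Lookup structures over a checklist (by name, genus and epithet)."""

    def __init__(self, checklist: Sequence[ChecklistTaxon]):
        self.taxa = list(checklist)
        self.by_name: dict[str, ChecklistTaxon] = {}
        self.by_genus: dict[str, list[ChecklistTaxon]] = {}
        self.by_epithet: dict[str, list[ChecklistTaxon]] = {}
        for t in self.taxa:
            self.by_name.setdefault(t.canonical_name, t)
            self.by_genus.setdefault(t.genus, []).append(t)
            self.by_epithet.setdefault(t.species_epithet, []).append(t)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def __len__(self) -> int:
        return len(self.by_name)


def _index(checklist: Sequence[ChecklistTaxon] | ChecklistIndex) -> ChecklistIndex:
    return checklist if isinstance(checklist, ChecklistIndex) else ChecklistIndex(checklist)


def resolve_name(
    name: str,
    checklist: Sequence[ChecklistTaxon] | ChecklistIndex,
    synonyms: Sequence[SynonymEntry] = (),
) -> NameResolution:
    """Resolve one species name against the checklist and synonym table.

    Pure function of its inputs; see the module docstring for the
    resolution order.
    """
    idx = _index(checklist)
    normalized = normalize_name(name)
    if not normalized or " " not in normalized:
        return NameResolution(input_name=name, status=ResolutionStatus.UNIDENTIFIED,
                              evidence="no species-level name")
    if normalized in idx:
        return NameResolution(
            input_name=name, status=ResolutionStatus.MATCHED, accepted_name=normalized,
            evidence="exact checklist match",
        )
    for entry in synonyms:
        if normalize_name(entry.variant_name) != normalized:
            continue
        accepted = normalize_name(entry.accepted_name)
        if entry.kind is SynonymKind.POST_CHECKLIST:
            return NameResolution(
                input_name=name, status=ResolutionStatus.POST_CHECKLIST,
                accepted_name=accepted,
                evidence="synonym table: described/reported after the checklist",
            )
        status = (
            ResolutionStatus.SYNONYM
            if entry.kind is SynonymKind.SYNONYM
            else ResolutionStatus.SPELLING_VARIANT
        )
        if accepted not in idx:
            # table promised a checklist anchor but the name is absent
            return NameResolution(
                input_name=name, status=ResolutionStatus.TENTATIVE_NEW,
                evidence=f"synonym table points at {accepted!r}, not in checklist",
            )
        return NameResolution(
            input_name=name, status=status, accepted_name=accepted,
            evidence=f"synonym table ({entry.kind.value})",
        )
    genus, epithet = normalized.split(" ", 1)
    best: tuple[int, int, ChecklistTaxon] | None = None
    for pos, taxon in enumerate(idx.by_genus.get(genus, ())):
        if _gender_swap(epithet, taxon.species_epithet):
            dist = 0  # exact-stem gender swap outranks edit-distance matches
        else:
            dist = _edit_distance(epithet, taxon.species_epithet)
            if dist > MAX_EDIT_DISTANCE:
                continue
        if best is None or (dist, pos) < best[:2]:
            best = (dist, pos, taxon)
    if best is not None:
        dist, _, taxon = best
        how = "gender-suffix swap" if dist == 0 else f"edit distance {dist}"
        return NameResolution(
            input_name=name, status=ResolutionStatus.SPELLING_VARIANT,
            accepted_name=taxon.canonical_name,
            evidence=f"spelling match in genus {genus} ({how})",
        )
    hint = ""
    same_epithet = [t.canonical_name for t in idx.by_epithet.get(epithet, ())]
    if same_epithet:
        hint = "; same epithet under " + ", ".join(same_epithet) + " (possible new combination)"
    return NameResolution(
        input_name=name, status=ResolutionStatus.TENTATIVE_NEW,
        evidence="absent from checklist and synonym table" + hint,
    )


def annotate_dataset(
    ds: Dataset,
    checklist: Sequence[ChecklistTaxon] | ChecklistIndex,
    synonyms: Sequence[SynonymEntry] = (),
) -> tuple[dict[str, NameResolution], dict[str, int]]:
    """Resolve every record's name; return per-record resolutions and
    species-level status counts.

    Counts are over distinct input species names (plus one UNIDENTIFIED
    bucket counted once if any record lacks a name), not over specimens:
    library accounting is species-based.
    """
    idx = _index(checklist)
    cache: dict[str, NameResolution] = {}
    per_record: dict[str, NameResolution] = {}
    for rec in ds:
        key = rec.species
        if key not in cache:
            cache[key] = resolve_name(key, idx, synonyms)
        per_record[rec.process_id] = cache[key]
    counts = Counter(res.status.value for res in cache.values())
    return per_record, {status.value: counts.get(status.value, 0) for status in ResolutionStatus}


def apply_resolutions(
    ds: Dataset, resolutions: Mapping[str, NameResolution]
) -> Dataset:
    """Return a dataset copy with resolution_status/accepted_name columns
    added to each record's extra fields (for the annotated-table writer)."""
    new_records = []
    for rec in ds:
        res = resolutions[rec.process_id]
        extra = dict(rec.extra)
        extra["resolution_status"] = res.status.value
        extra["accepted_name"] = res.accepted_name
        new_records.append(replace(rec, taxonomy=dict(rec.taxonomy), extra=extra))
    return Dataset(records=new_records, provenance=ds.provenance)


def accepted_species(
    resolutions: Mapping[str, NameResolution],
) -> dict[str, str]:
    """process_id -> accepted name, for records that resolved to the
    checklist or to a post-checklist name."""
    return {
        pid: res.accepted_name
        for pid, res in resolutions.items()
        if res.accepted_name
    }
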