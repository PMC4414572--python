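"""Concordance auditing and reference-library assembly.

A *bin* (OTU) is concordant when its named members carry exactly one
accepted species name, discordant with two or more, and unnamed with none.
Unnamed members never create discordance — bins made entirely of
unidentified specimens are reported separately as possible new species
records, not as conflicts.

Species are scored from the bin side: a species occurring only in
concordant bins is identifiable from its barcode; a species touching any
discordant bin shares barcodes with its partners; a species with named
specimens but no bin placement is unplaced.

The *library* is the audited subset of a data release: records that pass
the barcode data standard, whose names resolve to the checklist, and that
have a bin assignment.  Species are always counted by accepted
(post-reconciliation) name so that synonym pairs cannot fabricate
discordance.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bin_clustering import BinPartition
from .bold_io import ChecklistTaxon, Dataset, SpecimenRecord, SynonymEntry
from .sequence_metrics import (
    DivergenceSummary,
    QCConfig,
    compliance_check,
    flag_high_divergence,
    intraspecific_stats,
)
from .taxonomy_reconcile import (
    CHECKLIST_ANCHORED,
    ChecklistIndex,
    NameResolution,
    annotate_dataset,
)

logger = logging.getLogger(__name__)

NO_BIN = "NO_BIN"
NAME_UNRESOLVED = "NAME_UNRESOLVED"

NOT_ASSIGNED = "Not.assigned"


class BinStatus(str, Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    UNNAMED = "UNNAMED"


class SpeciesStatus(str, Enum):
    IDENTIFIABLE = "IDENTIFIABLE"
    SHARING = "SHARING"
    UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class BinConcordanceRecord:
    bin_id: str
    n_specimens: int
    species_names: frozenset[str]
    status: BinStatus
    singleton: bool

    @property
    def n_species(self) -> int:
        return len(self.species_names)


@dataclass(frozen=True)
class SpeciesStatusRecord:
    species: str
    n_specimens: int
    n_bins: int
    status: SpeciesStatus
    sharing_partners: frozenset[str]


@dataclass
class LibraryBuild:
    """The audited library subset plus the full exclusion ledger.

    ``excluded`` maps every rejected process ID to its complete reason list;
    the included records plus the excluded IDs partition the input dataset.
    Downstream summaries need the bin assignment and name resolutions that
    produced the build, so both ride along.
    """

    records: Dataset
    excluded: dict[str, list[str]]
    checklist_coverage: pd.DataFrame
    resolutions: dict[str, NameResolution] = field(default_factory=dict)
    partition: BinPartition | None = None
    qc: QCConfig = field(default_factory=QCConfig)

    def accepted_name(self, pid: str) -> str:
        res = self.resolutions.get(pid)
        return res.accepted_name if res else ""


def _named_members(
    members: Iterable[str], accepted: Mapping[str, str]
) -> dict[str, list[str]]:
    """accepted species name -> member process IDs (named members only)."""
    out: dict[str, list[str]] = defaultdict(list)
    for pid in members:
        name = accepted.get(pid, "")
        if name:
            out[name].append(pid)
    return dict(out)


def bin_concordance(
    assignment: Mapping[str, str], accepted: Mapping[str, str]
) -> list[BinConcordanceRecord]:
    """Classify every bin as concordant / discordant / unnamed.

    ``assignment`` maps process_id -> bin label (from a computed partition
    or from input bin_label fields); ``accepted`` maps process_id ->
    accepted species name, empty/absent for unidentified specimens.
    """
    bins: dict[str, list[str]] = defaultdict(list)
    for pid, label in assignment.items():
        bins[label].append(pid)
    out = []
    for label, members in bins.items():
        names = frozenset(_named_members(members, accepted))
        if not names:
            status = BinStatus.UNNAMED
        elif len(names) == 1:
            status = BinStatus.CONCORDANT
        else:
            status = BinStatus.DISCORDANT
        out.append(
            BinConcordanceRecord(
                bin_id=label,
                n_specimens=len(members),
                species_names=names,
                status=status,
                singleton=len(members) == 1,
            )
        )
    return out


def species_status(
    concordance: Sequence[BinConcordanceRecord],
    accepted: Mapping[str, str],
    assignment: Mapping[str, str],
) -> list[SpeciesStatusRecord]:
    """Three-way classification of every accepted species.

    IDENTIFIABLE: all of its bins concordant; SHARING: at least one bin
    discordant (partners listed); UNPLACED: named specimens but no bin.
    """
    by_bin = {rec.bin_id: rec for rec in concordance}
    species_bins: dict[str, set[str]] = defaultdict(set)
    species_specimens: dict[str, int] = defaultdict(int)
    for pid, name in accepted.items():
        if not name:
            continue
        species_specimens[name] += 1
        label = assignment.get(pid, "")
        if label:
            species_bins[name].add(label)
    out = []
    for name in sorted(species_specimens):
        bins = sorted(species_bins.get(name, ()))
        if not bins:
            status = SpeciesStatus.UNPLACED
            partners: frozenset[str] = frozenset()
        else:
            discordant = [b for b in bins if by_bin[b].status is BinStatus.DISCORDANT]
            if discordant:
                status = SpeciesStatus.SHARING
                partners = frozenset(
                    other
                    for b in discordant
                    for other in by_bin[b].species_names
                    if other != name
                )
            else:
                status = SpeciesStatus.IDENTIFIABLE
                partners = frozenset()
        out.append(
            SpeciesStatusRecord(
                species=name,
                n_specimens=species_specimens[name],
                n_bins=len(bins),
                status=status,
                sharing_partners=partners,
            )
        )
    return out


def unnamed_bins(
    concordance: Sequence[BinConcordanceRecord],
    ds: Dataset,
    assignment: Mapping[str, str],
    country_filter: str = "",
) -> list[BinConcordanceRecord]:
    """Bins with no named member: possible new species records.

    With a country filter, only bins holding at least one record collected
    in that country are returned.
    """
    unnamed = [rec for rec in concordance if rec.status is BinStatus.UNNAMED]
    if not country_filter:
        return unnamed
    by_id = ds.by_id()
    countries: dict[str, set[str]] = defaultdict(set)
    for pid, label in assignment.items():
        rec = by_id.get(pid)
        if rec is not None and rec.country:
            countries[label].add(rec.country)
    return [rec for rec in unnamed if country_filter in countries.get(rec.bin_id, ())]


def build_library(
    ds: Dataset,
    checklist: Sequence[ChecklistTaxon] | ChecklistIndex,
    synonyms: Sequence[SynonymEntry] = (),
    qc: QCConfig | None = None,
    partition: BinPartition | None = None,
) -> LibraryBuild:
    """Assemble the reference library and the exclusion ledger.

    Inclusion requires: QC pass, a name resolving into the checklist
    (matched, synonym, or spelling variant), and a bin assignment.  Excluded
    records carry every applicable reason code.  Rebuilding from the build's
    own records changes nothing (idempotence).
    """
    qc = qc or QCConfig()
    idx = checklist if isinstance(checklist, ChecklistIndex) else ChecklistIndex(checklist)
    resolutions, _ = annotate_dataset(ds, idx, synonyms)
    assignment = partition.assignment if partition is not None else {
        rec.process_id: rec.bin_label for rec in ds if rec.bin_label
    }
    included: list[SpecimenRecord] = []
    excluded: dict[str, list[str]] = {}
    for rec in ds:
        reasons = sorted(compliance_check(rec, qc).reasons)
        res = resolutions[rec.process_id]
        if res.status not in CHECKLIST_ANCHORED:
            reasons.append(NAME_UNRESOLVED)
        if rec.process_id not in assignment:
            reasons.append(NO_BIN)
        if reasons:
            excluded[rec.process_id] = reasons
            logger.info("excluded %s: %s", rec.process_id, ",".join(reasons))
        else:
            included.append(rec)
    library = Dataset(records=included, provenance=f"library<{ds.provenance}>")
    coverage = _checklist_coverage(library, resolutions, idx)
    return LibraryBuild(
        records=library,
        excluded=excluded,
        checklist_coverage=coverage,
        resolutions=resolutions,
        partition=partition,
        qc=qc,
    )


def _checklist_coverage(
    library: Dataset, resolutions: Mapping[str, NameResolution], idx: ChecklistIndex
) -> pd.DataFrame:
    barcoded: dict[str, set[str]] = defaultdict(set)
    for rec in library:
        name = resolutions[rec.process_id].accepted_name
        taxon = idx.by_name.get(name)
        if taxon is not None:
            barcoded[taxon.family].add(name)
    rows = []
    families: dict[str, list[ChecklistTaxon]] = defaultdict(list)
    for t in idx.taxa:
        families[t.family].append(t)
    for family, taxa in families.items():
        total = len({t.canonical_name for t in taxa})
        done = len(barcoded.get(family, ()))
        rows.append(
            {
                "suborder": taxa[0].suborder,
                "family": family,
                "checklist_species": total,
                "barcoded_species": done,
                "proportion": done / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["suborder", "family", "checklist_species",
                                       "barcoded_species", "proportion"])


def family_coverage(build: LibraryBuild, checklist: Sequence[ChecklistTaxon] | ChecklistIndex
                    ) -> pd.DataFrame:
    """Per-family species coverage, grouped by suborder then sorted by
    coverage proportion descending (the family-coverage figure's table)."""
    df = build.checklist_coverage.copy()
    return df.sort_values(
        ["suborder", "proportion", "family"], ascending=[True, False, True]
    ).reset_index(drop=True)


def _suborder_of(rec: SpecimenRecord, accepted: str, idx: ChecklistIndex) -> str:
    """Suborder bucket for summary roll-ups.

    A record whose accepted name is in the checklist must also carry
    consistent higher taxonomy (or none); a species name consistent with the
    checklist under inconsistent higher ranks is a workflow red flag and is
    bucketed as Not.assigned, as is anything unresolvable.
    """
    taxon = idx.by_name.get(accepted)
    if taxon is None:
        claimed = rec.taxonomy.get("suborder", "")
        if claimed and any(t.suborder == claimed for t in idx.taxa):
            return claimed
        return NOT_ASSIGNED
    claimed_family = rec.taxonomy.get("family", "")
    if claimed_family and claimed_family != taxon.family:
        return NOT_ASSIGNED
    claimed_suborder = rec.taxonomy.get("suborder", "")
    if claimed_suborder and claimed_suborder != taxon.suborder:
        return NOT_ASSIGNED
    return taxon.suborder


def suborder_summary(
    build: LibraryBuild,
    ds: Dataset,
    checklist: Sequence[ChecklistTaxon] | ChecklistIndex,
    divergence_metric: str = "k2p",
    divergence_threshold: float = 0.02,
) -> pd.DataFrame:
    """Ordinal-level roll-up of the data release and the library.

    One row per suborder plus a Totals row; columns cover library and
    release families/genera/species, bin counts (library, total, unnamed),
    species over the divergence threshold, specimen counts, and species
    sharing barcodes.  Column sums equal the Totals row by construction
    (asserted in tests, not here).
    """
    idx = checklist if isinstance(checklist, ChecklistIndex) else ChecklistIndex(checklist)
    resolutions = build.resolutions
    assignment = build.partition.assignment if build.partition else {}
    accepted = {pid: res.accepted_name for pid, res in resolutions.items()}
    lib_ids = {rec.process_id for rec in build.records}
    concordance = bin_concordance(assignment, accepted)
    lib_concordance = bin_concordance(
        {p: b for p, b in assignment.items() if p in lib_ids},
        {p: n for p, n in accepted.items() if p in lib_ids},
    )
    statuses = species_status(
        lib_concordance,
        {p: n for p, n in accepted.items() if p in lib_ids},
        {p: b for p, b in assignment.items() if p in lib_ids},
    )
    sharing_by_species = {s.species: s.status is SpeciesStatus.SHARING for s in statuses}

    lib_seqs: dict[str, dict[str, str]] = defaultdict(dict)
    for rec in build.records:
        name = accepted.get(rec.process_id, "")
        if name and rec.sequence:
            lib_seqs[name][rec.process_id] = rec.sequence
    flagged = {
        s.species
        for s in flag_high_divergence(
            intraspecific_stats(lib_seqs, metric=divergence_metric), divergence_threshold
        )
    }

    by_id = ds.by_id()

    def bucket(pid: str) -> str:
        return _suborder_of(by_id[pid], accepted.get(pid, ""), idx)

    suborders = sorted({t.suborder for t in idx.taxa} | {bucket(r.process_id) for r in ds})
    # species -> suborder (majority bucket of its specimens, first wins ties)
    rows = []
    for sub in suborders:
        release_ids = [r.process_id for r in ds if bucket(r.process_id) == sub]
        lib_sub_ids = [p for p in release_ids if p in lib_ids]
        rel_recs = [by_id[p] for p in release_ids]
        lib_recs = [by_id[p] for p in lib_sub_ids]
        lib_species = {accepted[p] for p in lib_sub_ids if accepted.get(p)}
        rel_species = {accepted[p] for p in release_ids if accepted.get(p)}
        lib_bins = {assignment[p] for p in lib_sub_ids if p in assignment}
        rel_bins = {assignment[p] for p in release_ids if p in assignment}
        unnamed = {
            c.bin_id
            for c in concordance
            if c.status is BinStatus.UNNAMED and c.bin_id in rel_bins
        }
        rows.append(
            {
                "suborder": sub,
                "lib_families": len({r.taxonomy["family"] for r in lib_recs if r.taxonomy["family"]}),
                "release_families": len({r.taxonomy["family"] for r in rel_recs if r.taxonomy["family"]}),
                "lib_genera": len({s.split()[0] for s in lib_species}),
                "release_genera": len({s.split()[0] for s in rel_species}),
                "lib_species": len(lib_species),
                "release_species": len(rel_species),
                "lib_bins": len(lib_bins),
                "total_bins": len(rel_bins),
                "unnamed_bins": len(unnamed),
                "high_divergence_species": len(lib_species & flagged),
                "lib_specimens": len(lib_sub_ids),
                "release_specimens": len(release_ids),
                "species_sharing": sum(
                    1 for s in lib_species if sharing_by_species.get(s, False)
                ),
            }
        )
    df = pd.DataFrame(rows)
    count_cols = [c for c in df.columns if c != "suborder"]
    totals = {"suborder": "Totals", **{c: int(df[c].sum()) for c in count_cols}}
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def concordance_histogram(
    concordance: Sequence[BinConcordanceRecord],
    ds: Dataset,
    assignment: Mapping[str, str],
    family_filter: frozenset[str] | set[str] = frozenset(),
    identifier_whitelist: frozenset[str] | set[str] = frozenset(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-bin (family, n_species, n_specimens) triples plus marginal counts
    of named bins holding 1, 2, and >=3 species.

    ``family_filter`` restricts to the given families (empty = all);
    ``identifier_whitelist``, when non-empty, restricts scope to bins with
    at least one member identified by a listed specialist (user-method IDs).
    """
    by_id = ds.by_id()
    members: dict[str, list[str]] = defaultdict(list)
    for pid, label in assignment.items():
        members[label].append(pid)

    def bin_family(label: str) -> str:
        fams = [by_id[p].taxonomy["family"] for p in members[label]
                if p in by_id and by_id[p].taxonomy["family"]]
        return max(set(fams), key=fams.count) if fams else ""

    def whitelisted(label: str) -> bool:
        if not identifier_whitelist:
            return True
        return any(
            p in by_id and by_id[p].identified_by in identifier_whitelist
            for p in members[label]
        )

    rows = []
    counts = {"1": 0, "2": 0, "3+": 0}
    for rec in concordance:
        if rec.status is BinStatus.UNNAMED:
            continue
        fam = bin_family(rec.bin_id)
        if family_filter and fam not in family_filter:
            continue
        if not whitelisted(rec.bin_id):
            continue
        rows.append({"family": fam, "n_species": rec.n_species,
                     "n_specimens": rec.n_specimens, "bin_id": rec.bin_id})
        if rec.n_species == 1:
            counts["1"] += 1
        elif rec.n_species == 2:
            counts["2"] += 1
        else:
            counts["3+"] += 1
    df = pd.DataFrame(rows, columns=["family", "n_species", "n_specimens", "bin_id"])
    return df, counts


def primer_success_matrix(ds: Dataset) -> pd.DataFrame:
    """Family x primer-pair amplification table: attempts, successes and the
    success proportion (success = a non-empty sequence).  Records lacking
    primer metadata are excluded, with the count logged."""
    skipped = 0
    cells: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for rec in ds:
        if not rec.primer_pair:
            skipped += 1
            continue
        key = (rec.taxonomy["family"], rec.primer_pair)
        cells[key][0] += 1
        if rec.sequence:
            cells[key][1] += 1
    if skipped:
        logger.info("primer matrix: %d records lacked primer metadata", skipped)
    rows = [
        {
            "family": fam,
            "primer_pair": primer,
            "attempts": att,
            "successes": succ,
            "proportion": succ / att,
        }
        for (fam, primer), (att, succ) in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["family", "primer_pair", "attempts",
                                       "successes", "proportion"])


def audit_report(
    build: LibraryBuild,
    ds: Dataset,
    checklist: Sequence[ChecklistTaxon] | ChecklistIndex,
    country_filter: str = "",
) -> dict:
    """Aggregate every audit count into one JSON-serializable report."""
    idx = checklist if isinstance(checklist, ChecklistIndex) else ChecklistIndex(checklist)
    accepted = {p: r.accepted_name for p, r in build.resolutions.items()}
    assignment = build.partition.assignment if build.partition else {}
    lib_ids = {rec.process_id for rec in build.records}
    lib_assignment = {p: b for p, b in assignment.items() if p in lib_ids}
    lib_accepted = {p: n for p, n in accepted.items() if p in lib_ids}
    concordance = bin_concordance(lib_assignment, lib_accepted)
    statuses = species_status(concordance, lib_accepted, lib_assignment)
    release_concordance = bin_concordance(assignment, accepted)
    unnamed = unnamed_bins(release_concordance, ds, assignment, country_filter)
    lib_seqs: dict[str, dict[str, str]] = defaultdict(dict)
    for rec in build.records:
        name = accepted.get(rec.process_id, "")
        if name and rec.sequence:
            lib_seqs[name][rec.process_id] = rec.sequence
    summaries = intraspecific_stats(lib_seqs, metric="k2p")
    flagged = flag_high_divergence(summaries)
    status_counts = {s.value: 0 for s in SpeciesStatus}
    for s in statuses:
        status_counts[s.status.value] += 1
    bin_counts = {b.value: 0 for b in BinStatus}
    for c in concordance:
        bin_counts[c.status.value] += 1
    return {
        "release_records": len(ds),
        "library_records": len(build.records),
        "excluded_records": len(build.excluded),
        "library_species": len({n for n in lib_accepted.values() if n}),
        "library_genera": len({n.split()[0] for n in lib_accepted.values() if n}),
        "library_bins": len({b for b in lib_assignment.values()}),
        "release_bins": len({b for b in assignment.values()}),
        "bin_status": bin_counts,
        "species_status": status_counts,
        "unnamed_bins": len(unnamed),
        "high_divergence_species": len(flagged),
        "singleton_bins": sum(1 for c in concordance if c.singleton),
        "exclusion_reasons": _reason_tally(build.excluded),
    }


def _reason_tally(excluded: Mapping[str, Sequence[str]]) -> dict[str, int]:
    tally: dict[str, int] = defaultdict(int)
    for reasons in excluded.values():
        for r in reasons:
            tally[r] += 1
    return dict(tally)


def write_audit_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_exclusions(excluded: Mapping[str, Sequence[str]], path: str | Path) -> None:
    pd.DataFrame(
        [(pid, ";".join(reasons)) for pid, reasons in excluded.items()],
        columns=["process_id", "reasons"],
    ).to_csv(path, sep="\t", index=False)
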