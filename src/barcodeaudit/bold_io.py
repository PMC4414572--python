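"""Readers and writers for BOLD-style specimen tables, checklists, synonym
tables and FASTA files.

BOLD exports have drifted across the years ("processid" vs "Process ID",
"nucleotides" vs "nuc"); a configurable alias table maps whatever headers a
download carries onto the typed :class:`SpecimenRecord` fields.  Unmapped
columns are preserved verbatim in ``SpecimenRecord.extra`` so nothing from a
download is lost on a round trip.

Conventions applied on read:

* sequences are uppercased; terminal gap characters are stripped, internal
  gaps are kept (they carry alignment information);
* missing metadata is the empty string, never ``None`` or a sentinel;
* ``process_id`` must be unique within a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TAXONOMY_RANKS = ("phylum", "class", "order", "suborder", "family", "genus", "species")

#: IUPAC nucleotide codes plus gap; everything a barcode sequence may contain.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Default header alias table: canonical field -> accepted column names.
#: Matching is case-insensitive and ignores spaces/underscores/dots.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "process_id": ("processid", "process_id", "process id"),
    "sample_id": ("sampleid", "sample_id", "sample id"),
    "institution": ("institution_storing", "institution", "inst"),
    "phylum": ("phylum_name", "phylum"),
    "class": ("class_name", "class"),
    "order": ("order_name", "order"),
    "suborder": ("suborder_name", "suborder", "subfamily_name"),
    "family": ("family_name", "family"),
    "genus": ("genus_name", "genus"),
    "species": ("species_name", "species"),
    "identified_by": ("identification_provided_by", "identified_by", "identifier"),
    "identification_method": ("identification_method", "id_method"),
    "bin_label": ("bin_uri", "bin.uri", "bin_label", "bin"),
    "country": ("country", "country_ocean"),
    "collection_year": ("collection_year", "collectdate_year", "year"),
    "primer_pair": ("seq_primers", "primer_pair", "primers"),
    "sequence": ("nucleotides", "nuc", "sequence"),
}


class IdentificationMethod(str, Enum):
    """How a specimen obtained its taxonomic name.

    BOLD names come from the data submitter, from an institutional unit-tray
    placement, or from the platform's sequence-match engine.
    """

    USER = "user"
    INSTITUTIONAL = "institutional"
    ID_ENGINE = "id_engine"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, raw: str) -> "IdentificationMethod":
        token = raw.strip().lower()
        if not token:
            return cls.UNKNOWN
        if "institution" in token or "curator" in token:
            return cls.INSTITUTIONAL
        if "engine" in token or "bin" in token or "bold id" in token:
            return cls.ID_ENGINE
        if token in {"user", "morphology", "morphological", "taxonomist", "specialist"}:
            return cls.USER
        return cls.UNKNOWN


class ParseError(ValueError):
    """A table could not be mapped onto the typed schema."""


class DuplicateProcessIDError(ParseError):
    def __init__(self, offenders: Sequence[str]):
        self.offenders = list(offenders)
        super().__init__(
            "duplicate process_id values: " + ", ".join(sorted(set(self.offenders)))
        )


@dataclass
class SpecimenRecord:
    """One specimen row: identifiers, taxonomy, metadata and its barcode."""

    process_id: str
    sample_id: str = ""
    institution: str = ""
    taxonomy: dict[str, str] = field(default_factory=dict)
    identified_by: str = ""
    identification_method: IdentificationMethod = IdentificationMethod.UNKNOWN
    bin_label: str = ""
    country: str = ""
    collection_year: int | None = None
    primer_pair: str = ""
    sequence: str = ""
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.process_id:
            raise ParseError("SpecimenRecord requires a non-empty process_id")
        for rank in TAXONOMY_RANKS:
            self.taxonomy.setdefault(rank, "")
        bad = set(self.sequence.upper()) - IUPAC_CODES
        if bad:
            raise ParseError(
                f"{self.process_id}: sequence contains non-IUPAC characters {sorted(bad)}"
            )

    @property
    def species(self) -> str:
        return self.taxonomy.get("species", "")


@dataclass(frozen=True)
class ChecklistTaxon:
    """One accepted species with its higher ranks (the nomenclatural baseline)."""

    suborder: str
    family: str
    genus: str
    species_epithet: str
    author: str = ""

    @property
    def canonical_name(self) -> str:
        return f"{self.genus} {self.species_epithet}"


class SynonymKind(str, Enum):
    SYNONYM = "synonym"
    SPELLING = "spelling"
    POST_CHECKLIST = "post_checklist"


@dataclass(frozen=True)
class SynonymEntry:
    """A known name variant mapped to an accepted (or post-checklist) name."""

    variant_name: str
    accepted_name: str
    kind: SynonymKind


@dataclass
class Dataset:
    """An ordered collection of specimen records with a provenance label."""

    records: list[SpecimenRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        dupes = []
        for rec in self.records:
            seen[rec.process_id] = seen.get(rec.process_id, 0) + 1
            if seen[rec.process_id] == 2:
                dupes.append(rec.process_id)
        if dupes:
            raise DuplicateProcessIDError(dupes)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, SpecimenRecord]:
        return {rec.process_id: rec for rec in self.records}

    def sequences(self) -> dict[str, str]:
        """Mapping process_id -> sequence for records that carry one."""
        return {rec.process_id: rec.sequence for rec in self.records if rec.sequence}


def _canon_header(name: str) -> str:
    return "".join(ch for ch in name.strip().lower() if ch not in " _.")


def _build_header_map(
    columns: Iterable[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    """Map canonical field name -> actual column name present in the table."""
    canon_to_actual = {_canon_header(c): c for c in columns}
    out: dict[str, str] = {}
    for fieldname, names in aliases.items():
        for alias in names:
            actual = canon_to_actual.get(_canon_header(alias))
            if actual is not None:
                out[fieldname] = actual
                break
    return out


def normalize_sequence(raw: str) -> str:
    """Uppercase and strip terminal gaps; internal gaps are retained."""
    return raw.strip().upper().strip("-")


def _cell(row: pd.Series, col: str | None) -> str:
    if col is None:
        return ""
    val = row.get(col, "")
    if pd.isna(val):
        return ""
    return str(val).strip()


def read_specimen_table(
    path: str | Path,
    dialect: str = "tsv",
    aliases: Mapping[str, tuple[str, ...]] | None = None,
    provenance: str = "",
) -> Dataset:
    """Read a BOLD-style delimited specimen table into a typed :class:`Dataset`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    dialect:
        ``"tsv"`` (default) or ``"csv"``.
    aliases:
        Header alias table; defaults to :data:`COLUMN_ALIASES`.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])
    aliases = aliases or COLUMN_ALIASES
    header_map = _build_header_map(df.columns, aliases)
    if "process_id" not in header_map:
        raise ParseError(
            f"{path}: no process-ID column found among {list(df.columns)}"
        )
    mapped_cols = set(header_map.values())
    records: list[SpecimenRecord] = []
    for idx, row in df.iterrows():
        pid = _cell(row, header_map["process_id"])
        if not pid:
            raise ParseError(f"{path}: row {idx + 2} has an empty process ID")
        year_text = _cell(row, header_map.get("collection_year"))
        try:
            year = int(float(year_text)) if year_text else None
        except ValueError:
            year = None
        taxonomy = {rank: _cell(row, header_map.get(rank)) for rank in TAXONOMY_RANKS}
        records.append(
            SpecimenRecord(
                process_id=pid,
                sample_id=_cell(row, header_map.get("sample_id")),
                institution=_cell(row, header_map.get("institution")),
                taxonomy=taxonomy,
                identified_by=_cell(row, header_map.get("identified_by")),
                identification_method=IdentificationMethod.parse(
                    _cell(row, header_map.get("identification_method"))
                ),
                bin_label=_cell(row, header_map.get("bin_label")),
                country=_cell(row, header_map.get("country")),
                collection_year=year,
                primer_pair=_cell(row, header_map.get("primer_pair")),
                sequence=normalize_sequence(_cell(row, header_map.get("sequence"))),
                extra={c: _cell(row, c) for c in df.columns if c not in mapped_cols},
            )
        )
    return Dataset(records=records, provenance=provenance or str(path))


#: Column order used when writing specimen tables (legacy BOLD header names).
_WRITE_COLUMNS = [
    ("processid", lambda r: r.process_id),
    ("sampleid", lambda r: r.sample_id),
    ("institution_storing", lambda r: r.institution),
    ("phylum_name", lambda r: r.taxonomy["phylum"]),
    ("class_name", lambda r: r.taxonomy["class"]),
    ("order_name", lambda r: r.taxonomy["order"]),
    ("suborder_name", lambda r: r.taxonomy["suborder"]),
    ("family_name", lambda r: r.taxonomy["family"]),
    ("genus_name", lambda r: r.taxonomy["genus"]),
    ("species_name", lambda r: r.taxonomy["species"]),
    ("identification_provided_by", lambda r: r.identified_by),
    ("identification_method", lambda r: r.identification_method.value),
    ("bin_uri", lambda r: r.bin_label),
    ("country", lambda r: r.country),
    ("collection_year", lambda r: "" if r.collection_year is None else str(r.collection_year)),
    ("seq_primers", lambda r: r.primer_pair),
    ("nucleotides", lambda r: r.sequence),
]


def write_specimen_table(ds: Dataset, path: str | Path, dialect: str = "tsv") -> None:
    """Write a dataset back out as BOLD-style delimited text (UTF-8)."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    extra_cols = sorted({k for rec in ds for k in rec.extra})
    rows = []
    for rec in ds:
        row = {name: getter(rec) for name, getter in _WRITE_COLUMNS}
        for col in extra_cols:
            row[col] = rec.extra.get(col, "")
        rows.append(row)
    cols = [name for name, _ in _WRITE_COLUMNS] + extra_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_checklist(path: str | Path, dialect: str = "csv") -> list[ChecklistTaxon]:
    """Read a taxonomic checklist (suborder, family, genus, species rows).

    Rows lacking a genus or species epithet are rejected with a logged warning
    carrying their line number; duplicated canonical names are deduplicated
    (first occurrence wins).  File order is preserved.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])
    header_map = _build_header_map(
        df.columns,
        {
            "suborder": ("suborder",),
            "family": ("family",),
            "genus": ("genus",),
            "species": ("species", "species_epithet", "epithet"),
            "author": ("author", "authority"),
        },
    )
    missing = {"suborder", "family", "genus", "species"} - set(header_map)
    if missing:
        raise ParseError(f"{path}: checklist lacks columns {sorted(missing)}")
    taxa: list[ChecklistTaxon] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        genus = _cell(row, header_map["genus"])
        epithet = _cell(row, header_map["species"])
        if not genus or not epithet:
            logger.warning("%s: line %d lacks genus or epithet; row rejected", path, idx + 2)
            continue
        taxon = ChecklistTaxon(
            suborder=_cell(row, header_map["suborder"]),
            family=_cell(row, header_map["family"]),
            genus=genus,
            species_epithet=epithet.lower(),
            author=_cell(row, header_map.get("author")),
        )
        if taxon.canonical_name in seen:
            logger.warning(
                "%s: line %d duplicates %s; ignored", path, idx + 2, taxon.canonical_name
            )
            continue
        seen.add(taxon.canonical_name)
        taxa.append(taxon)
    if not taxa:
        logger.warning("%s: checklist is empty", path)
    return taxa


def write_checklist(taxa: Sequence[ChecklistTaxon], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "suborder": t.suborder,
                "family": t.family,
                "genus": t.genus,
                "species": t.species_epithet,
                "author": t.author,
            }
            for t in taxa
        ],
        columns=["suborder", "family", "genus", "species", "author"],
    ).to_csv(path, index=False, encoding="utf-8")


def read_synonyms(path: str | Path) -> list[SynonymEntry]:
    """Read a synonym/variant table (variant_name, accepted_name, kind)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    required = {"variant_name", "accepted_name", "kind"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: synonym table needs columns {sorted(required)}")
    return [
        SynonymEntry(
            variant_name=str(row["variant_name"]).strip(),
            accepted_name=str(row["accepted_name"]).strip(),
            kind=SynonymKind(str(row["kind"]).strip()),
        )
        for _, row in df.iterrows()
    ]


def write_synonyms(entries: Sequence[SynonymEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"variant_name": e.variant_name, "accepted_name": e.accepted_name, "kind": e.kind.value}
            for e in entries
        ],
        columns=["variant_name", "accepted_name", "kind"],
    ).to_csv(path, index=False, encoding="utf-8")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA of barcodes keyed by bare process ID (order-preserving)."""
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        pid = rec.id.strip()
        if not pid:
            raise ParseError(f"{path}: record {i} has a malformed (empty) header")
        if pid in out:
            raise DuplicateProcessIDError([pid])
        out[pid] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write sequences with bare process-ID headers; round-trips with read_fasta."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
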