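"""Synthetic BOLD-style datasets with known species and cluster truth.

The generator emulates the statistical structure a barcode audit relies on:
many species with low intraspecific and much higher interspecific COI
divergence, transition-biased substitutions, a fraction of unidentified
specimens, planted misspellings and synonyms, sub-length and ambiguity-rich
sequences, and species deliberately forced to share a haplotype cluster.

Sequences are generated as an ancestral 658 bp barcode per species;
interspecific divergence is guaranteed by giving each species a private set
of diagnostic sites, and specimens then accumulate substitutions with a
transition/transversion rate bias kappa at the remaining sites.  No indels
are introduced, matching the equal-length comparison contract of real
COI-5P barcodes within an order.

Every planted artifact is recorded in a truth ledger so a closed-loop test
can check that each one is reported by exactly the stage that should catch
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .bold_io import (
    ChecklistTaxon,
    Dataset,
    IdentificationMethod,
    SpecimenRecord,
    SynonymEntry,
    SynonymKind,
    write_checklist,
    write_fasta,
    write_specimen_table,
    write_synonyms,
)

_BASES = np.array(list("ACGT"))
#: transition partner of A,C,G,T under the 0..3 encoding
_TRANSITION = np.array([2, 3, 0, 1])

_SYLLABLES = ["ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ra",
              "su", "ta", "ve", "xo", "zu"]

_FAMILY_POOL = [
    ("Heteroptera", "Miridae"),
    ("Heteroptera", "Lygaeidae"),
    ("Sternorrhyncha", "Aphididae"),
    ("Sternorrhyncha", "Psyllidae"),
    ("Clypeorrhyncha", "Cicadellidae"),
]

_PRIMER_POOL = ["LepF1_LepR1", "LCO1490_HCO2198", "MLepF1_LepR1"]
_INSTITUTIONS = ["CNC", "BIO", "ROM"]


class SimulationError(ValueError):
    """The requested divergence structure cannot be generated."""


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic barcode dataset.

    Defaults model a well-separated fauna: ~0.5% within-species divergence
    against a >=6% between-species floor (comfortably astride the 2.2%
    clustering threshold), transition bias kappa=3 as typical for insect
    mitochondrial COI, and a modest load of curation artifacts.
    """

    n_species: int = 20
    specimens_per_species: tuple[int, int] = (3, 8)
    seq_length: int = 658
    intra_divergence: float = 0.005
    inter_divergence: float = 0.06
    kappa: float = 3.0
    fraction_unidentified: float = 0.1
    n_synonym_pairs: int = 2
    n_misspellings: int = 2
    n_noncompliant: int = 3
    sharing_groups: list[list[int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.intra_divergence, self.inter_divergence,
                     self.fraction_unidentified):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must lie in [0, 1]")
        if self.inter_divergence <= 2 * self.intra_divergence:
            raise SimulationError(
                "inter_divergence must exceed twice intra_divergence for "
                "cluster recovery to be well-posed"
            )
        lo, hi = self.specimens_per_species
        if lo < 1 or hi < lo:
            raise SimulationError("specimens_per_species must be a valid range")


def _species_name(i: int) -> tuple[str, str]:
    """Deterministic pronounceable (genus, epithet) pair for species i."""
    n = len(_SYLLABLES)
    genus = ("".join(_SYLLABLES[(i // 7 + k) % n] for k in (0, 3, 6))).capitalize()
    epithet = "".join(_SYLLABLES[(i + k * 5) % n] for k in (1, 2, 4)) + _SYLLABLES[i % n]
    return genus, epithet


def _mutate(codes: np.ndarray, sites: np.ndarray, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute the given sites with transition bias kappa (ti:tv rate)."""
    out = codes.copy()
    p_ts = kappa / (kappa + 2.0)
    for s in sites:
        if rng.random() < p_ts:
            out[s] = _TRANSITION[out[s]]
        else:
            # one of the two transversion partners, uniformly
            tv = [b for b in range(4) if b != out[s] and b != _TRANSITION[out[s]]]
            out[s] = tv[rng.integers(2)]
    return out


def simulate_sequences(cfg: SimulationConfig) -> dict:
    """Generate per-species ancestors and specimen sequences.

    Returns a dict with ``species`` (canonical names in order), ``truth``
    (process_id -> species name), ``sequences`` (process_id -> str),
    ``cluster_truth`` (process_id -> cluster ordinal after merging sharing
    groups), and the realized divergence extremes.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    # diagnostic block per effective cluster: two clusters differing in
    # m sites each sit >= 2m/L apart
    m = int(np.ceil(cfg.inter_divergence * L / 2.0)) + 1

    # merge sharing groups into effective clusters
    cluster_of = list(range(cfg.n_species))
    for group in cfg.sharing_groups:
        if any(i >= cfg.n_species for i in group):
            raise SimulationError("sharing group references unknown species index")
        head = min(group)
        for i in group:
            cluster_of[i] = head
    clusters = sorted(set(cluster_of))
    if len(clusters) * m > L:
        raise SimulationError(
            f"cannot fit {len(clusters)} clusters x {m} diagnostic sites into {L} bp"
        )
    root = rng.integers(0, 4, size=L)
    blocks = rng.permutation(L)[: len(clusters) * m].reshape(len(clusters), m)
    diagnostic = set(blocks.ravel().tolist())
    free_sites = np.array([s for s in range(L) if s not in diagnostic])
    ancestors: dict[int, np.ndarray] = {}
    for k, cluster in enumerate(clusters):
        ancestors[cluster] = _mutate(root, blocks[k], cfg.kappa, rng)

    species_names = [" ".join(_species_name(i)) for i in range(cfg.n_species)]
    truth: dict[str, str] = {}
    cluster_truth: dict[str, int] = {}
    sequences: dict[str, str] = {}
    lo, hi = cfg.specimens_per_species
    n_intra = max(1, round(cfg.intra_divergence * L / 2.0))
    pid_no = 0
    for i in range(cfg.n_species):
        anc = ancestors[cluster_of[i]]
        for _ in range(int(rng.integers(lo, hi + 1))):
            pid_no += 1
            pid = f"SYNHE{pid_no:04d}"
            sites = rng.choice(free_sites, size=rng.integers(0, n_intra + 1),
                               replace=False)
            codes = _mutate(anc, sites, cfg.kappa, rng)
            sequences[pid] = "".join(_BASES[codes])
            truth[pid] = species_names[i]
            cluster_truth[pid] = clusters.index(cluster_of[i])
    realized = _realized_divergences(sequences, truth, cluster_truth)
    return {
        "species": species_names,
        "truth": truth,
        "cluster_truth": cluster_truth,
        "sequences": sequences,
        **realized,
    }


def _realized_divergences(sequences, truth, cluster_truth) -> dict:
    """Realized max within-cluster and min between-cluster p-distance."""
    from .sequence_metrics import encode_sequence, p_distance

    pids = list(sequences)
    codes = {p: encode_sequence(sequences[p]) for p in pids}
    max_intra, min_inter = 0.0, 1.0
    for i, a in enumerate(pids):
        for b in pids[i + 1:]:
            d = p_distance(codes[a], codes[b]).p_dist
            if cluster_truth[a] == cluster_truth[b]:
                max_intra = max(max_intra, d)
            else:
                min_inter = min(min_inter, d)
    return {"realized_max_intra": max_intra, "realized_min_inter": min_inter}


def _checklist_for(species_names: Sequence[str]) -> list[ChecklistTaxon]:
    taxa = []
    for i, name in enumerate(species_names):
        genus, epithet = name.split()
        suborder, family = _FAMILY_POOL[(i // 7) % len(_FAMILY_POOL)]
        taxa.append(ChecklistTaxon(suborder=suborder, family=family, genus=genus,
                                   species_epithet=epithet))
    return taxa


def _misspell(epithet: str, rng: np.random.Generator) -> str:
    """Perturb an epithet by 1-2 edits (delete last letter and/or swap one)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    variant = list(epithet)
    n_edits = int(rng.integers(1, 3))
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(variant)))
        if op == 0 and len(variant) > 4:
            variant.pop(pos)
        elif op == 1:
            old = variant[pos]
            choices = [c for c in letters if c != old]
            variant[pos] = choices[int(rng.integers(len(choices)))]
        else:
            variant.insert(pos, letters[int(rng.integers(26))])
    return "".join(variant)


def _variant_synonym_name(i: int) -> str:
    genus = ("".join(_SYLLABLES[(i * 3 + k) % len(_SYLLABLES)]
                     for k in (2, 5, 8))).capitalize() + "ops"
    epithet = "".join(_SYLLABLES[(i * 5 + k * 2) % len(_SYLLABLES)] for k in (0, 1, 3))
    return f"{genus} {epithet}"


@dataclass
class TruthLedger:
    """Every planted fact, with the stage expected to report it."""

    species: list[str]
    truth: dict[str, str]              # pid -> true species (pre-artifact)
    cluster_truth: dict[str, int]      # pid -> true cluster ordinal
    n_clusters: int
    realized_max_intra: float
    realized_min_inter: float
    synonym_species: dict[str, str] = field(default_factory=dict)   # variant -> accepted
    misspelled_species: dict[str, str] = field(default_factory=dict)  # variant -> accepted
    unidentified_pids: list[str] = field(default_factory=list)
    fully_unidentified_species: list[str] = field(default_factory=list)
    noncompliant: dict[str, str] = field(default_factory=dict)       # pid -> reason code
    sharing_groups: list[list[str]] = field(default_factory=list)    # species names

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def inject_artifacts(
    ds: Dataset, cfg: SimulationConfig, ledger: TruthLedger,
    rng: np.random.Generator,
) -> Dataset:
    """Plant synonyms, misspellings, unidentified specimens and
    QC-noncompliant sequences; update the ledger in place.

    Species are drawn without overlap: a species is touched by at most one
    name artifact, so every planted fact has exactly one expected detector.
    """
    from .sequence_metrics import NO_SEQUENCE, TOO_AMBIGUOUS, TOO_SHORT

    records = {rec.process_id: rec for rec in ds}
    by_species: dict[str, list[str]] = {}
    for rec in ds:
        by_species.setdefault(rec.species, []).append(rec.process_id)

    # sharing-group species are reserved: each planted fact must have exactly
    # one expected detector, and blanking or renaming a sharing species would
    # entangle the sharing signal with a name artifact
    reserved = {sp for group in ledger.sharing_groups for sp in group}
    species_pool = [sp for sp in ledger.species if sp not in reserved]
    need = cfg.n_synonym_pairs + cfg.n_misspellings + 1
    if need > len(species_pool):
        raise SimulationError("not enough species for the requested artifacts")
    picked = rng.choice(len(species_pool), size=need, replace=False)
    syn_targets = [species_pool[i] for i in picked[: cfg.n_synonym_pairs]]
    misspell_targets = [
        species_pool[i]
        for i in picked[cfg.n_synonym_pairs: cfg.n_synonym_pairs + cfg.n_misspellings]
    ]
    blank_species = species_pool[picked[-1]] if cfg.fraction_unidentified > 0 else None

    # synonyms: all records of the species carry the variant name
    for j, target in enumerate(syn_targets):
        variant = _variant_synonym_name(j)
        ledger.synonym_species[variant] = target
        for pid in by_species[target]:
            rec = records[pid]
            tax = dict(rec.taxonomy)
            tax["species"] = variant
            tax["genus"] = variant.split()[0]
            records[pid] = replace(rec, taxonomy=tax)

    # misspellings: edit-distance-1..2 perturbation of the epithet
    for target in misspell_targets:
        genus, epithet = target.split()
        variant_ep = _misspell(epithet, rng)
        while variant_ep == epithet:
            variant_ep = _misspell(epithet, rng)
        variant = f"{genus} {variant_ep}"
        ledger.misspelled_species[variant] = target
        for pid in by_species[target]:
            rec = records[pid]
            tax = dict(rec.taxonomy)
            tax["species"] = variant
            records[pid] = replace(rec, taxonomy=tax)

    # unidentified specimens: blank one whole species first (guaranteeing an
    # unnamed cluster), then random singles up to the configured fraction
    if cfg.fraction_unidentified > 0 and blank_species is not None:
        target_n = round(cfg.fraction_unidentified * len(ds.records))
        blanked: list[str] = []
        for pid in by_species[blank_species]:
            blanked.append(pid)
        ledger.fully_unidentified_species.append(blank_species)
        touched = set(blanked) | {
            p for t in syn_targets + misspell_targets for p in by_species[t]
        }
        candidates = [p for p in records if p not in touched]
        extra = max(0, target_n - len(blanked))
        if extra:
            picked_pids = rng.choice(len(candidates), size=min(extra, len(candidates)),
                                     replace=False)
            blanked.extend(candidates[i] for i in sorted(picked_pids))
        for pid in blanked:
            rec = records[pid]
            tax = dict(rec.taxonomy)
            tax["species"] = ""
            tax["genus"] = ""
            records[pid] = replace(rec, taxonomy=tax)
        ledger.unidentified_pids = sorted(blanked)

    # QC failures: cycle short / ambiguous / missing sequences
    untouched = [p for p in records
                 if p not in ledger.unidentified_pids
                 and records[p].species not in ledger.synonym_species
                 and records[p].species not in ledger.misspelled_species]
    if cfg.n_noncompliant > len(untouched):
        raise SimulationError("not enough records left for noncompliant artifacts")
    picked_pids = rng.choice(len(untouched), size=cfg.n_noncompliant, replace=False)
    for k, i in enumerate(sorted(picked_pids)):
        pid = untouched[i]
        rec = records[pid]
        if k % 3 == 0:
            seq = rec.sequence[:480]
            reason = TOO_SHORT
        elif k % 3 == 1:
            n_amb = int(np.ceil(0.012 * len(rec.sequence)))
            seq = "N" * n_amb + rec.sequence[n_amb:]
            reason = TOO_AMBIGUOUS
        else:
            seq = ""
            reason = NO_SEQUENCE
        ledger.noncompliant[pid] = reason
        records[pid] = replace(rec, sequence=seq)

    return Dataset(records=[records[rec.process_id] for rec in ds],
                   provenance=ds.provenance)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[Dataset, list[ChecklistTaxon], list[SynonymEntry], TruthLedger]:
    """Full synthetic study: sequences, metadata, artifacts, and the ledger."""
    sim = simulate_sequences(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # metadata/artifact stream
    checklist = _checklist_for(sim["species"])
    by_name = {t.canonical_name: t for t in checklist}
    records = []
    for pid, seq in sim["sequences"].items():
        species = sim["truth"][pid]
        taxon = by_name[species]
        records.append(
            SpecimenRecord(
                process_id=pid,
                sample_id=f"S-{pid}",
                institution=_INSTITUTIONS[int(rng.integers(len(_INSTITUTIONS)))],
                taxonomy={
                    "phylum": "Arthropoda",
                    "class": "Insecta",
                    "order": "Hemiptera",
                    "suborder": taxon.suborder,
                    "family": taxon.family,
                    "genus": taxon.genus,
                    "species": species,
                },
                identified_by="Simulated Determiner",
                identification_method=IdentificationMethod.USER,
                country="Canada" if rng.random() < 0.9 else "United States",
                collection_year=int(rng.integers(1990, 2014)),
                primer_pair=_PRIMER_POOL[int(rng.integers(len(_PRIMER_POOL)))],
                sequence=seq,
            )
        )
    ds = Dataset(records=records, provenance=f"synthetic(seed={cfg.seed})")
    n_clusters = len(set(sim["cluster_truth"].values()))
    ledger = TruthLedger(
        species=sim["species"],
        truth=sim["truth"],
        cluster_truth=sim["cluster_truth"],
        n_clusters=n_clusters,
        realized_max_intra=sim["realized_max_intra"],
        realized_min_inter=sim["realized_min_inter"],
        sharing_groups=[[sim["species"][i] for i in g] for g in cfg.sharing_groups],
    )
    ds = inject_artifacts(ds, cfg, ledger, rng)
    synonyms = [
        SynonymEntry(variant_name=v, accepted_name=a, kind=SynonymKind.SYNONYM)
        for v, a in ledger.synonym_species.items()
    ]
    return ds, checklist, synonyms, ledger


def write_simulation(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path, Path]:
    """Emit the interchange files the readers consume, plus the ledger.

    Returns paths (specimens.tsv, sequences.fasta, checklist.csv,
    synonyms.csv, truth_ledger.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, checklist, synonyms, ledger = simulate_dataset(cfg)
    paths = (
        outdir / "specimens.tsv",
        outdir / "sequences.fasta",
        outdir / "checklist.csv",
        outdir / "synonyms.csv",
        outdir / "truth_ledger.json",
    )
    write_specimen_table(ds, paths[0])
    write_fasta(ds.sequences(), paths[1])
    write_checklist(checklist, paths[2])
    write_synonyms(synonyms, paths[3])
    paths[4].write_text(ledger.to_json() + "\n")
    return paths
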