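import numpy as np
import pytest

from barcodeaudit.bold_io import (
    ChecklistTaxon,
    Dataset,
    SpecimenRecord,
    SynonymEntry,
    SynonymKind,
)
from barcodeaudit.synthetic_fixtures import SimulationConfig, simulate_dataset


def make_record(pid, species="", seq="", genus="", family="", suborder="",
                country="Canada", primer="LepF1_LepR1", **kwargs):
    """Terse specimen-record factory for fixtures."""
    if species and not genus:
        genus = species.split()[0]
    taxonomy = {
        "order": "Hemiptera",
        "suborder": suborder,
        "family": family,
        "genus": genus,
        "species": species,
    }
    return SpecimenRecord(
        process_id=pid,
        sample_id=f"S{pid}",
        taxonomy=taxonomy,
        country=country,
        primer_pair=primer,
        sequence=seq,
        **kwargs,
    )


def random_sequence(rng, length=658):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutated(seq, rng, n_subs):
    """Substitute n_subs random sites with a different base."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def checklist():
    return [
        ChecklistTaxon("Heteroptera", "Miridae", "Lygus", "lineolaris", "Palisot"),
        ChecklistTaxon("Heteroptera", "Miridae", "Lygus", "elisus"),
        ChecklistTaxon("Heteroptera", "Miridae", "Tropidosteptes", "cardinalis", "Uhler"),
        ChecklistTaxon("Heteroptera", "Miridae", "Plagiognathus", "obscurus"),
        ChecklistTaxon("Sternorrhyncha", "Aphididae", "Aphis", "pomi"),
        ChecklistTaxon("Sternorrhyncha", "Aphididae", "Aphis", "rubicola"),
        ChecklistTaxon("Clypeorrhyncha", "Cicadellidae", "Macrosteles", "quadrilineatus"),
    ]


@pytest.fixture(scope="session")
def synonyms():
    return [
        SynonymEntry("Neolygus vetustus", "Lygus lineolaris", SynonymKind.SYNONYM),
        SynonymEntry("Aphis pomii", "Aphis pomi", SynonymKind.SPELLING),
        SynonymEntry("Kelisia recens", "Kelisia recens", SynonymKind.POST_CHECKLIST),
    ]


@pytest.fixture(scope="session")
def simulated():
    """The study-condition synthetic dataset: 20 species, ~0.5% intra,
    >=6% inter, seed 42, with one forced sharing pair."""
    cfg = SimulationConfig(seed=42, sharing_groups=[[0, 1]])
    ds, checklist, synonyms, ledger = simulate_dataset(cfg)
    return {"cfg": cfg, "ds": ds, "checklist": checklist,
            "synonyms": synonyms, "ledger": ledger}


@pytest.fixture(scope="session")
def simulated_clean():
    """Artifact-free simulation for pure clustering tests."""
    cfg = SimulationConfig(seed=42, fraction_unidentified=0.0,
                           n_synonym_pairs=0, n_misspellings=0, n_noncompliant=0)
    ds, checklist, synonyms, ledger = simulate_dataset(cfg)
    return {"cfg": cfg, "ds": ds, "checklist": checklist,
            "synonyms": synonyms, "ledger": ledger}
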