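"""Concordance classification, library assembly and summary tables."""

import numpy as np
import pytest

from barcodeaudit.bin_clustering import BinPartition
from barcodeaudit.bold_io import ChecklistTaxon, Dataset
from barcodeaudit.library_audit import (
    NAME_UNRESOLVED,
    NO_BIN,
    BinStatus,
    SpeciesStatus,
    audit_report,
    bin_concordance,
    build_library,
    concordance_histogram,
    family_coverage,
    primer_success_matrix,
    species_status,
    suborder_summary,
    unnamed_bins,
)
from barcodeaudit.sequence_metrics import QCConfig

from conftest import make_record, random_sequence


def conc(assignment, accepted):
    return {c.bin_id: c for c in bin_concordance(assignment, accepted)}


class TestBinConcordance:
    def test_single_species_concordant(self):
        c = conc({"a": "B1", "b": "B1", "c": "B1"},
                 {"a": "Sp a", "b": "Sp a", "c": "Sp a"})["B1"]
        assert c.status is BinStatus.CONCORDANT and c.n_species == 1

    def test_two_species_discordant(self):
        c = conc({"a": "B1", "b": "B1"}, {"a": "Sp a", "b": "Sp b"})["B1"]
        assert c.status is BinStatus.DISCORDANT and c.n_species == 2

    def test_unnamed_members_never_create_discordance(self):
        assignment = {p: "B1" for p in "abcde"}
        c = conc(assignment, {"a": "Sp a"})["B1"]
        assert c.status is BinStatus.CONCORDANT
        assert c.n_specimens == 5

    def test_fully_unnamed_bin(self):
        c = conc({"a": "B1", "b": "B1"}, {})["B1"]
        assert c.status is BinStatus.UNNAMED and c.n_species == 0

    def test_singleton_flag(self):
        records = conc({"a": "B1", "b": "B2", "c": "B2"}, {"a": "Sp a"})
        assert records["B1"].singleton and not records["B2"].singleton

    def test_status_partition_is_exhaustive(self):
        assignment = {"a": "B1", "b": "B1", "c": "B2", "d": "B3"}
        accepted = {"a": "Sp a", "b": "Sp b", "c": "Sp c"}
        statuses = [c.status for c in bin_concordance(assignment, accepted)]
        assert len(statuses) == 3
        assert sorted(s.value for s in statuses) == [
            "CONCORDANT", "DISCORDANT", "UNNAMED"]


class TestSpeciesStatus:
    def test_identifiable_single_concordant_bin(self):
        assignment = {"a": "B1", "b": "B1"}
        accepted = {"a": "Sp a", "b": "Sp a"}
        (s,) = species_status(bin_concordance(assignment, accepted),
                              accepted, assignment)
        assert s.status is SpeciesStatus.IDENTIFIABLE and s.n_bins == 1

    def test_identifiable_across_two_concordant_bins(self):
        # a deeply split species still identifiable when both bins are clean
        assignment = {"a": "B1", "b": "B2"}
        accepted = {"a": "Sp a", "b": "Sp a"}
        (s,) = species_status(bin_concordance(assignment, accepted),
                              accepted, assignment)
        assert s.status is SpeciesStatus.IDENTIFIABLE and s.n_bins == 2

    def test_sharing_lists_partners(self):
        assignment = {"a": "B1", "b": "B1", "c": "B2"}
        accepted = {"a": "Sp a", "b": "Sp b", "c": "Sp a"}
        by_name = {s.species: s for s in species_status(
            bin_concordance(assignment, accepted), accepted, assignment)}
        assert by_name["Sp a"].status is SpeciesStatus.SHARING
        assert by_name["Sp a"].sharing_partners == {"Sp b"}
        assert by_name["Sp b"].sharing_partners == {"Sp a"}

    def test_unplaced_species_without_bin(self):
        accepted = {"a": "Sp a"}
        (s,) = species_status([], accepted, {})
        assert s.status is SpeciesStatus.UNPLACED and s.n_bins == 0

    def test_three_way_identity(self):
        assignment = {"a": "B1", "b": "B1", "c": "B2", "d": "B2"}
        accepted = {"a": "Sp a", "b": "Sp b", "c": "Sp c", "d": "Sp c",
                    "e": "Sp d"}
        statuses = species_status(bin_concordance(assignment, accepted),
                                  accepted, assignment)
        tally = {status: 0 for status in SpeciesStatus}
        for s in statuses:
            tally[s.status] += 1
        assert sum(tally.values()) == len({n for n in accepted.values()}) == 4
        assert tally[SpeciesStatus.SHARING] == 2
        assert tally[SpeciesStatus.UNPLACED] == 1


class TestUnnamedBins:
    def make(self):
        ds = Dataset(records=[
            make_record("a", "", "ACGT" * 150, country="Canada"),
            make_record("b", "", "ACGT" * 150, country="Canada"),
            make_record("c", "", "ACGT" * 150, country="United States"),
            make_record("d", "Sp a", "ACGT" * 150, country="Canada"),
        ])
        assignment = {"a": "B1", "b": "B1", "c": "B2", "d": "B3"}
        return ds, assignment, bin_concordance(
            assignment, {"d": "Sp a"})

    def test_unnamed_listed_named_excluded(self):
        ds, assignment, concordance = self.make()
        found = {c.bin_id for c in unnamed_bins(concordance, ds, assignment)}
        assert found == {"B1", "B2"}

    def test_country_filter(self):
        ds, assignment, concordance = self.make()
        found = {c.bin_id
                 for c in unnamed_bins(concordance, ds, assignment, "Canada")}
        assert found == {"B1"}


@pytest.fixture
def audit_fixture(rng, checklist):
    """20 records: 4 QC failures, 2 unresolvable names, rest clean."""
    species_cycle = ["Lygus lineolaris", "Lygus elisus", "Aphis pomi",
                     "Macrosteles quadrilineatus"]
    taxa = {t.canonical_name: t for t in checklist}
    records = []
    for i in range(20):
        pid = f"P{i:02d}"
        if i < 4:
            seq = random_sequence(rng, 300)   # QC: too short
        else:
            seq = random_sequence(rng, 658)
        if i in (4, 5):
            name = "Unknownus inventus"       # unresolvable
            records.append(make_record(pid, name, seq))
            continue
        name = species_cycle[i % 4]
        t = taxa[name]
        records.append(make_record(pid, name, seq, family=t.family,
                                   suborder=t.suborder))
    ds = Dataset(records=records)
    assignment = {r.process_id: f"B{i % 4}" for i, r in enumerate(records)}
    partition = BinPartition(assignment=assignment, threshold=0.022)
    return ds, partition


class TestBuildLibrary:
    def test_counts_and_reasons(self, audit_fixture, checklist):
        ds, partition = audit_fixture
        build = build_library(ds, checklist, partition=partition)
        assert len(build.records) == 14
        assert len(build.excluded) == 6
        assert set(build.excluded) == {f"P{i:02d}" for i in range(6)}
        assert all("TOO_SHORT" in build.excluded[f"P{i:02d}"] for i in range(4))
        for pid in ("P04", "P05"):
            assert NAME_UNRESOLVED in build.excluded[pid]

    def test_empty_dataset_empty_build(self, checklist):
        build = build_library(Dataset(records=[]), checklist)
        assert len(build.records) == 0 and build.excluded == {}

    def test_qc_pass_but_unidentified_excluded(self, rng, checklist):
        ds = Dataset(records=[make_record("u1", "", random_sequence(rng, 658))])
        partition = BinPartition(assignment={"u1": "B1"}, threshold=0.022)
        build = build_library(ds, checklist, partition=partition)
        assert build.excluded["u1"] == ["NO_SPECIES", NAME_UNRESOLVED]

    def test_idempotent(self, audit_fixture, checklist):
        ds, partition = audit_fixture
        first = build_library(ds, checklist, partition=partition)
        second = build_library(first.records, checklist, partition=partition)
        assert [r.process_id for r in second.records] == \
               [r.process_id for r in first.records]
        assert second.excluded == {}

    def test_library_subset_of_release(self, audit_fixture, checklist):
        ds, partition = audit_fixture
        build = build_library(ds, checklist, partition=partition)
        release = ds.by_id()
        for rec in build.records:
            assert rec == release[rec.process_id]
        assert len(build.records) + len(build.excluded) == len(ds)


class TestSummaries:
    def test_suborder_totals_equal_column_sums(self, audit_fixture, checklist):
        ds, partition = audit_fixture
        build = build_library(ds, checklist, partition=partition)
        table = suborder_summary(build, ds, checklist)
        totals = table[table.suborder == "Totals"].iloc[0]
        body = table[table.suborder != "Totals"]
        for col in table.columns:
            if col != "suborder":
                assert totals[col] == body[col].sum()

    def test_single_suborder_dataset_totals_equal_row(self, rng):
        checklist = [ChecklistTaxon("Heteroptera", "Miridae", "Lygus", "lineolaris")]
        ds = Dataset(records=[
            make_record("a", "Lygus lineolaris", random_sequence(rng, 658),
                        family="Miridae", suborder="Heteroptera")])
        partition = BinPartition(assignment={"a": "B1"}, threshold=0.022)
        build = build_library(ds, checklist, partition=partition)
        table = suborder_summary(build, ds, checklist)
        row = table[table.suborder == "Heteroptera"].iloc[0]
        totals = table[table.suborder == "Totals"].iloc[0]
        for col in table.columns:
            if col != "suborder":
                assert totals[col] == row[col]

    def test_checklist_inconsistent_higher_taxonomy_not_assigned(self, rng):
        checklist = [ChecklistTaxon("Heteroptera", "Miridae", "Lygus", "lineolaris")]
        # species name matches the checklist but family contradicts it
        ds = Dataset(records=[
            make_record("a", "Lygus lineolaris", random_sequence(rng, 658),
                        family="Aphididae", suborder="Sternorrhyncha")])
        partition = BinPartition(assignment={"a": "B1"}, threshold=0.022)
        build = build_library(ds, checklist, partition=partition)
        table = suborder_summary(build, ds, checklist)
        row = table[table.suborder == "Not.assigned"].iloc[0]
        assert row["release_specimens"] == 1

    def test_family_coverage_proportions(self, audit_fixture, checklist):
        ds, partition = audit_fixture
        build = build_library(ds, checklist, partition=partition)
        table = family_coverage(build, checklist)
        by_family = table.set_index("family")
        # Miridae: 4 checklist species, 2 barcoded (lineolaris, elisus)
        assert by_family.loc["Miridae", "checklist_species"] == 4
        assert by_family.loc["Miridae", "barcoded_species"] == 2
        assert by_family.loc["Miridae", "proportion"] == pytest.approx(0.5)
        # Cicadellidae fully covered; family with no data -> 0.0 never occurs
        assert by_family.loc["Cicadellidae", "proportion"] == 1.0
        assert ((table.proportion >= 0) & (table.proportion <= 1)).all()

    def test_family_absent_from_data_zero_coverage(self, rng, checklist):
        ds = Dataset(records=[make_record("a", "Lygus lineolaris",
                                          random_sequence(rng, 658))])
        partition = BinPartition(assignment={"a": "B1"}, threshold=0.022)
        build = build_library(ds, checklist, partition=partition)
        table = family_coverage(build, checklist).set_index("family")
        assert table.loc["Aphididae", "barcoded_species"] == 0
        assert table.loc["Aphididae", "proportion"] == 0.0


class TestConcordanceHistogram:
    def make(self):
        ds = Dataset(records=[
            make_record("a", "Sp a", family="Miridae"),
            make_record("b", "Sp a", family="Miridae"),
            make_record("c", "Sp b", family="Miridae"),
            make_record("d", "Sp c", family="Aphididae"),
            make_record("e", "Sp d", family="Aphididae"),
            make_record("f", "Sp e", family="Aphididae"),
            make_record("g", "", family="Aphididae"),
        ])
        assignment = {"a": "B1", "b": "B1", "c": "B2",
                      "d": "B3", "e": "B3", "f": "B3", "g": "B4"}
        accepted = {r.process_id: r.species for r in ds if r.species}
        return ds, assignment, bin_concordance(assignment, accepted)

    def test_counts_sum_to_named_bins(self):
        ds, assignment, concordance = self.make()
        triples, counts = concordance_histogram(concordance, ds, assignment)
        named = sum(1 for c in concordance if c.status is not BinStatus.UNNAMED)
        assert counts["1"] + counts["2"] + counts["3+"] == named == len(triples)
        assert counts == {"1": 2, "2": 0, "3+": 1}

    def test_family_filter(self):
        ds, assignment, concordance = self.make()
        triples, counts = concordance_histogram(
            concordance, ds, assignment, family_filter={"Miridae"})
        assert set(triples.family) == {"Miridae"}
        assert counts == {"1": 2, "2": 0, "3+": 0}

    def test_all_concordant_fixture(self):
        assignment = {"a": "B1", "b": "B2"}
        accepted = {"a": "Sp a", "b": "Sp b"}
        ds = Dataset(records=[make_record("a", "Sp a", family="F"),
                              make_record("b", "Sp b", family="F")])
        _, counts = concordance_histogram(
            bin_concordance(assignment, accepted), ds, assignment)
        assert counts == {"1": 2, "2": 0, "3+": 0}


class TestPrimerMatrix:
    def test_proportions(self, rng):
        records = []
        for i in range(10):  # 7 with sequence, 3 without
            records.append(make_record(
                f"m{i}", "Sp a", random_sequence(rng, 658) if i < 7 else "",
                family="Miridae", primer="LepF1_LepR1"))
        records.append(make_record("x0", "Sp b", random_sequence(rng, 658),
                                   family="Aphididae", primer="LCO_HCO"))
        table = primer_success_matrix(Dataset(records=records))
        cell = table.set_index(["family", "primer_pair"])
        assert cell.loc[("Miridae", "LepF1_LepR1"), "attempts"] == 10
        assert cell.loc[("Miridae", "LepF1_LepR1"), "proportion"] == pytest.approx(0.7)
        assert cell.loc[("Aphididae", "LCO_HCO"), "proportion"] == 1.0

    def test_records_without_primer_excluded(self):
        ds = Dataset(records=[make_record("a", "Sp a", "ACGT" * 150, primer="")])
        assert primer_success_matrix(ds).empty


def test_audit_report_identities(simulated):
    """Cross-cutting identities on the simulated study: species and bin
    status partitions are exhaustive."""
    from barcodeaudit.bin_clustering import assign_bins
    from barcodeaudit.sequence_metrics import compliant_sequences

    ds, checklist, synonyms = (simulated["ds"], simulated["checklist"],
                               simulated["synonyms"])
    partition = assign_bins(compliant_sequences(ds))
    build = build_library(ds, checklist, synonyms, partition=partition)
    report = audit_report(build, ds, checklist)
    assert sum(report["species_status"].values()) == report["library_species"]
    assert sum(report["bin_status"].values()) == report["library_bins"]
    assert report["library_records"] + report["excluded_records"] == len(ds)
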