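"""Assignment filters, taxonomy collapsing, noise filter, contaminants."""

import numpy as np
import pandas as pd
import pytest

from qmiseq import (
    AssignmentRecord,
    ReadTable,
    RegionalChecklist,
    StandardSpec,
    TaxonLabel,
    apply_blast_filters,
    classify_habitat,
    collapse_assignments,
    filter_pipeline,
    noise_filter,
    remove_contaminants,
)

CHECKLIST = RegionalChecklist(
    [
        "Scomber japonicus",
        "Scomber australasicus",
        "Acanthopagrus schlegelii",
        "Pagrus major",
    ]
)


def _table(counts: dict, standards=("Std_A", "Std_B")) -> ReadTable:
    df = pd.DataFrame(counts).T
    df.index.name = "sample_id"
    return ReadTable(df, standards)


class TestBlastFilters:
    @pytest.mark.parametrize(
        "identity,length,group,kept,reason",
        [
            (98.5, 172, "bony_fish", True, None),  # identity boundary kept
            (98.4, 172, "bony_fish", False, "low_identity"),
            (99.9, 150, "bony_fish", False, "short_alignment"),  # ≤150 dropped
            (99.9, 151, "bony_fish", True, None),
            (100.0, 172, "other", False, "non_fish"),
            (100.0, 172, "shark", True, None),
            (100.0, 172, "ray", True, None),
        ],
    )
    def test_drop_rules_and_boundaries(self, identity, length, group, kept, reason):
        rec = AssignmentRecord("otu1", ("Pagrus major",), identity, length, group)
        kept_list, dropped = apply_blast_filters([rec])
        if kept:
            assert kept_list == [rec] and not dropped
        else:
            assert not kept_list and dropped[0][1] == reason

    def test_partition_is_complete(self):
        recs = [
            AssignmentRecord(f"o{i}", ("Pagrus major",), 97 + i, 140 + 10 * i)
            for i in range(4)
        ]
        kept, dropped = apply_blast_filters(recs)
        assert len(kept) + len(dropped) == len(recs)


class TestCollapse:
    def test_single_hit_keeps_species_rank(self):
        rec = AssignmentRecord("o1", ("Pagrus major",), 100, 172)
        label = collapse_assignments(rec, CHECKLIST)
        assert label == TaxonLabel("o1", "Pagrus major", "species")

    def test_congeneric_pair_collapses_to_genus_spp(self):
        rec = AssignmentRecord(
            "o2", ("Scomber japonicus", "Scomber australasicus"), 99.5, 172
        )
        label = collapse_assignments(rec, CHECKLIST)
        assert label.name == "Scomber spp." and label.rank == "genus_spp"

    def test_single_regional_species_rescues_species_rank(self):
        rec = AssignmentRecord(
            "o3", ("Acanthopagrus schlegelii", "Acanthopagrus sivicolus"), 99.0, 172
        )
        label = collapse_assignments(rec, CHECKLIST)
        assert label == TaxonLabel("o3", "Acanthopagrus schlegelii", "species")

    def test_multi_genus_falls_back_to_higher_rank(self):
        rec = AssignmentRecord("o4", ("Pagrus major", "Dentex tumifrons"), 99.0, 172)
        label = collapse_assignments(
            rec, CHECKLIST, genus_to_family={"Pagrus": "Sparidae",
                                            "Dentex": "Sparidae"}
        )
        assert label.rank == "higher" and label.name == "Sparidae"

    def test_label_never_outside_hits_or_checklist(self):
        rec = AssignmentRecord(
            "o5", ("Scomber japonicus", "Scomber australasicus"), 99.0, 172
        )
        label = collapse_assignments(rec, CHECKLIST)
        allowed = set(rec.hit_species) | {"Scomber spp."}
        assert label.name in allowed

    def test_unlisted_species_kept_with_warning(self, caplog):
        rec = AssignmentRecord("o6", ("Beryx splendens",), 100, 172)
        with caplog.at_level("WARNING"):
            label = collapse_assignments(rec, CHECKLIST)
        assert label.name == "Beryx splendens"
        assert "checklist" in caplog.text


class TestNoiseFilter:
    def test_threshold_boundary_at_half_permille(self):
        """Sample totalling 100,000 fish reads: 49 zeroed, 50 kept."""
        counts = {
            "s1": {"otu_a": 99_901, "otu_b": 49, "otu_c": 50,
                   "Std_A": 500, "Std_B": 250},
        }
        table = _table(counts)
        out = noise_filter(table)
        assert out.counts.loc["s1", "otu_b"] == 0
        assert out.counts.loc["s1", "otu_c"] == 50
        assert out.counts.loc["s1", "Std_A"] == 500  # standards untouched

    def test_singletons_always_removed_at_depth(self):
        counts = {"s1": {"otu_a": 99_999, "otu_b": 1, "Std_A": 10, "Std_B": 5}}
        out = noise_filter(_table(counts))
        assert out.counts.loc["s1", "otu_b"] == 0

    def test_all_zero_sample_unchanged(self):
        counts = {"s1": {"otu_a": 0, "otu_b": 0, "Std_A": 10, "Std_B": 5}}
        out = noise_filter(_table(counts))
        pd.testing.assert_frame_equal(out.counts, _table(counts).counts)

    def test_idempotent_and_never_increases(self, bundle):
        once = noise_filter(bundle.read_table)
        twice = noise_filter(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert (once.counts.to_numpy() <= bundle.read_table.counts.to_numpy()).all()
        assert list(once.counts.columns) == list(bundle.read_table.counts.columns)
        assert list(once.counts.index) == list(bundle.read_table.counts.index)

    def test_denominator_option_includes_standards(self):
        # fish total 1000, standards 99_000: with standards in the total the
        # threshold is 50 instead of 0.5
        counts = {"s1": {"otu_a": 960, "otu_b": 40,
                         "Std_A": 66_000, "Std_B": 33_000}}
        keep_fish_denominator = noise_filter(_table(counts))
        assert keep_fish_denominator.counts.loc["s1", "otu_b"] == 40
        with_std = noise_filter(_table(counts), include_standards_in_total=True)
        assert with_std.counts.loc["s1", "otu_b"] == 0


class TestContaminants:
    def test_blocklisted_taxon_column_removed(self):
        counts = {"s1": {"Oncorhynchus nerka": 10, "Pagrus major": 20,
                         "Std_A": 5, "Std_B": 5}}
        out = remove_contaminants(_table(counts))
        assert "Oncorhynchus nerka" not in out.counts.columns
        assert "Pagrus major" in out.counts.columns

    def test_empty_blocklist_is_identity(self):
        counts = {"s1": {"Oncorhynchus nerka": 10, "Std_A": 5, "Std_B": 5}}
        out = remove_contaminants(_table(counts), blocklist=frozenset())
        pd.testing.assert_frame_equal(out.counts, _table(counts).counts)

    def test_absent_taxon_is_noop(self):
        counts = {"s1": {"Pagrus major": 20, "Std_A": 5, "Std_B": 5}}
        out = remove_contaminants(_table(counts))
        pd.testing.assert_frame_equal(out.counts, _table(counts).counts)

    def test_matching_via_labels(self):
        counts = {"s1": {"OTU_1": 10, "OTU_2": 20, "Std_A": 5, "Std_B": 5}}
        labels = {
            "OTU_1": TaxonLabel("OTU_1", "Trachurus trachurus", "species"),
            "OTU_2": TaxonLabel("OTU_2", "Trachurus japonicus", "species"),
        }
        out = remove_contaminants(_table(counts), labels=labels)
        assert list(out.fish_ids) == ["OTU_2"]


class TestHabitat:
    def test_lookup_and_default(self, caplog):
        lbl = TaxonLabel("o1", "Pagrus major", "species")
        assert classify_habitat(lbl, {"Pagrus major": "demersal"}) == "demersal"
        with caplog.at_level("WARNING"):
            assert classify_habitat(lbl, {}) == "demersal"
        assert "defaulting" in caplog.text

    def test_partition_sums_to_total(self, bundle, quantified):
        qt, _ = quantified
        habitat = bundle.species_info["habitat"]
        otu_habitat = {}
        for rec in bundle.assignments:
            lbl = collapse_assignments(
                rec, RegionalChecklist(list(bundle.species_info.index))
            )
            otu_habitat[rec.otu_id] = classify_habitat(
                lbl, habitat.to_dict(), default="demersal"
            )
        ml = qt.copies_per_ml_water
        dem = ml[[o for o, h in otu_habitat.items() if h == "demersal"]].sum(axis=1)
        pel = ml[[o for o, h in otu_habitat.items() if h == "pelagic"]].sum(axis=1)
        assert np.allclose(dem + pel, ml.sum(axis=1))


class TestPipelineOrder:
    def test_pipeline_runs_in_order_and_audits_every_otu(self, bundle):
        checklist = RegionalChecklist(list(bundle.species_info.index))
        table, labels, audit = filter_pipeline(
            bundle.read_table, bundle.assignments, checklist
        )
        assert set(audit.index) == {r.otu_id for r in bundle.assignments}
        assert set(table.fish_ids) == set(labels)
        assert (audit["status"].isin(["kept", "dropped"])).all()
        # standards survive untouched
        std = list(bundle.standards.ids)
        pd.testing.assert_frame_equal(
            table.counts[std], bundle.read_table.counts[std]
        )
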