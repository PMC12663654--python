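"""Dicer gate, category rule table, deduplication and summaries."""

import pytest

from dicer_atlas.dcr_classifier import (
    CATEGORIES,
    DcrRecord,
    build_record,
    classify,
    dcr_gate,
    deduplicate,
    round_half_up,
    share_percentages,
    summarize,
    summarize_counts,
    terminal_lengths,
)
from dicer_atlas.domain_hits import Architecture, DomainHit


def arch_from_labels(labels, protein_length=2000):
    """Architecture with one well-spaced hit per listed label."""
    hits = []
    pos = 50
    for label in labels:
        hits.append(DomainHit("p", label, pos, pos + 80, 1e-10, 100.0))
        pos += 200
    return Architecture("p", protein_length, sorted(hits, key=lambda h: h.start))


#: unit pattern (HEL, DUF283, PAZ, dsRBD present?) -> expected category,
#: written out independently of the implementation's rule table
PATTERN_EXPECTATIONS = {
    (1, 1, 1, 1): "canonical",
    (1, 1, 1, 0): "nonA",
    (1, 1, 0, 1): "nonB",
    (0, 1, 1, 0): "nonC",
    (1, 1, 0, 0): "nonD",
    # everything else is the E catch-all
    (1, 0, 1, 1): "nonE", (0, 0, 1, 1): "nonE", (0, 1, 0, 1): "nonE",
    (1, 0, 0, 1): "nonE", (0, 1, 1, 1): "nonE", (1, 0, 1, 0): "nonE",
    (0, 0, 0, 1): "nonE", (0, 0, 1, 0): "nonE", (0, 1, 0, 0): "nonE",
    (1, 0, 0, 0): "nonE", (0, 0, 0, 0): "nonE",
}


def arch_from_pattern(hel, duf, paz, dsrbd):
    labels = ["RNaseIII", "RNaseIII"]
    if hel:
        labels = ["DEAD", "ResIII", "HeliC"] + labels
    if duf:
        labels.insert(-2, "DUF283")
    if paz:
        labels.insert(-2, "PAZ")
    if dsrbd:
        labels.append("dsRBD")
    return arch_from_labels(labels)


class TestGate:
    def test_tandem_rnase3_plus_duf283_passes(self):
        assert dcr_gate(arch_from_labels(["DUF283", "RNaseIII", "RNaseIII"]))

    def test_tandem_rnase3_alone_fails(self):
        assert not dcr_gate(arch_from_labels(["RNaseIII", "RNaseIII"]))

    def test_single_rnase3_fails_despite_rna_binding_domains(self):
        assert not dcr_gate(arch_from_labels(["PAZ", "DUF283", "RNaseIII"]))


class TestClassify:
    def test_full_complement_is_canonical(self):
        arch = arch_from_labels(["DEAD", "ResIII", "HeliC", "DUF283", "PAZ",
                                 "RNaseIII", "RNaseIII", "dsRBD"])
        assert classify(arch) == "canonical"

    def test_missing_paz_and_dsrbd_is_nonD(self):
        arch = arch_from_labels(["DEAD", "ResIII", "HeliC", "DUF283",
                                 "RNaseIII", "RNaseIII"])
        assert classify(arch) == "nonD"

    def test_duf283_and_tandem_only_is_nonE(self):
        assert classify(arch_from_labels(["DUF283", "RNaseIII", "RNaseIII"])) == "nonE"

    def test_rule_table_over_all_sixteen_unit_patterns(self):
        """Exhaustive enumeration: each gate-passing unit pattern gets
        exactly the expected category; all-absent fails the gate."""
        for pattern, expected in PATTERN_EXPECTATIONS.items():
            arch = arch_from_pattern(*pattern)
            if pattern == (0, 0, 0, 0):
                assert not dcr_gate(arch)
                continue
            assert dcr_gate(arch)
            assert classify(arch) == expected, pattern

    def test_categories_partition_gate_passing_patterns(self):
        seen = set()
        for pattern in PATTERN_EXPECTATIONS:
            if pattern == (0, 0, 0, 0):
                continue
            seen.add(classify(arch_from_pattern(*pattern)))
        assert seen == set(CATEGORIES)

    def test_classify_rejects_non_dcr(self):
        with pytest.raises(ValueError, match="non-Dcr"):
            classify(arch_from_labels(["RNaseIII", "RNaseIII"]))

    def test_classification_invariant_to_hit_order_and_decoys(self):
        from dicer_atlas.domain_hits import assemble_architecture, filter_hits
        hits = [
            DomainHit("p", "DUF283", 300, 380, 1e-12, 90.0),
            DomainHit("p", "RNaseIII", 500, 600, 1e-15, 120.0),
            DomainHit("p", "RNaseIII", 650, 750, 1e-14, 110.0),
            DomainHit("p", "PAZ", 400, 470, 1e-9, 60.0),
        ]
        decoy = DomainHit("p", "dsRBD", 800, 860, 0.05, 9.0)
        for ordering in (hits, hits[::-1], hits[2:] + hits[:2]):
            arch = assemble_architecture(
                "p", 1000, filter_hits(list(ordering) + [decoy]))
            assert classify(arch) == "nonC"  # DUF283+PAZ+IIIa/b: no HEL, no dsRBD


class TestTerminalLengths:
    def test_worked_example(self):
        hits = [DomainHit("p", "DUF283", 300, 380, 1e-12),
                DomainHit("p", "RNaseIII", 500, 600, 1e-15),
                DomainHit("p", "RNaseIII", 650, 750, 1e-14)]
        arch = Architecture("p", 1000, hits)
        assert terminal_lengths(arch) == (299, 250)

    def test_boundary_zero_lengths(self):
        hits = [DomainHit("p", "DUF283", 1, 80, 1e-12),
                DomainHit("p", "RNaseIII", 100, 200, 1e-15),
                DomainHit("p", "RNaseIII", 210, 300, 1e-14)]
        arch = Architecture("p", 300, hits)
        assert terminal_lengths(arch) == (0, 0)

    def test_undefined_without_landmarks(self):
        arch = Architecture("p", 500, [DomainHit("p", "RNaseIII", 10, 90, 1e-9)])
        assert terminal_lengths(arch) == (None, None)


def make_record(pid, species="sp1", seq="MAAA", uniprot="U1", **kw):
    arch = Architecture(pid, 2000, [])
    return DcrRecord(arch=arch, species=species, sequence=seq,
                     uniprot_id=uniprot, **kw)


class TestDeduplicate:
    def test_annotation_duplicates_collapse_to_smallest_accession(self):
        records = [make_record("XP_002"), make_record("XP_001")]
        kept = deduplicate(records)
        assert [r.protein_id for r in kept] == ["XP_001"]

    def test_isoforms_with_different_sequence_kept(self):
        records = [make_record("XP_001", seq="MAAA", gene_id="g1", locus="l1"),
                   make_record("XP_002", seq="MAAAEXTRA", gene_id="g1", locus="l1")]
        assert len(deduplicate(records)) == 2

    def test_identical_sequence_across_species_kept(self):
        records = [make_record("XP_001", species="sp1"),
                   make_record("XP_002", species="sp2")]
        assert len(deduplicate(records)) == 2

    def test_singleton_and_idempotence(self):
        records = [make_record("XP_001"), make_record("XP_002"),
                   make_record("YP_001", species="sp2")]
        once = deduplicate(records)
        assert deduplicate(once) == once
        assert len(once) == 2

    def test_missing_metadata_passes_through(self):
        records = [make_record("XP_001", uniprot=None),
                   make_record("XP_001", uniprot=None)]
        assert len(deduplicate(records)) == 2


class TestSummaries:
    # the survey's printed per-category Dcr counts
    COUNTS = {"canonical": 35, "nonA": 80, "nonB": 356,
              "nonC": 273, "nonD": 1825, "nonE": 342}

    def test_category_shares_match_hand_arithmetic(self):
        summary = summarize_counts(self.COUNTS)
        assert summary.total == 2911
        assert summary.percentages["canonical"] == 1.2
        assert summary.percentages["nonA"] == 2.7
        assert summary.percentages["nonB"] == 12.2
        assert summary.percentages["nonC"] == 9.4
        assert summary.percentages["nonD"] == 62.7

    def test_cpaz_lacking_aggregate(self):
        summary = summarize_counts(self.COUNTS)
        assert summary.cpaz_lacking_percent == 86.7

    def test_single_category_is_100_percent(self):
        summary = summarize_counts({"nonD": 7})
        assert summary.percentages["nonD"] == 100.0

    def test_percentages_sum_to_100_within_rounding(self):
        summary = summarize_counts(self.COUNTS)
        assert abs(sum(summary.percentages.values()) - 100.0) <= 0.2

    def test_summarize_records_counts_and_phylum_table(self):
        records = []
        layouts = {
            "nonD": ["DEAD", "ResIII", "HeliC", "DUF283", "RNaseIII", "RNaseIII"],
            "canonical": ["DEAD", "ResIII", "HeliC", "DUF283", "PAZ",
                          "RNaseIII", "RNaseIII", "dsRBD"],
        }
        for i, (cat, labels) in enumerate(
                [("nonD", layouts["nonD"]), ("nonD", layouts["nonD"]),
                 ("canonical", layouts["canonical"])]):
            arch = arch_from_labels(labels)
            rec = build_record(arch, species=f"sp{i}", phylum="Ascomycota")
            assert rec.category == cat
            records.append(rec)
        summary = summarize(records)
        assert summary.counts["nonD"] == 2
        assert summary.by_phylum.loc["Ascomycota", "canonical"] == 1
        assert int(summary.copy_number_histogram.loc[1, "n_proteomes"]) == 3

    def test_round_half_up_at_the_boundary(self):
        assert round_half_up(62.65, 1) == 62.7
        assert round_half_up(11.7485, 1) == 11.7
        assert round_half_up(11.68, 0) == 12.0

    def test_share_percentages_rejects_empty(self):
        with pytest.raises(ValueError):
            share_percentages({})
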