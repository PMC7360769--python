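"""Domain types, table I/O, alignment, and results serialization."""

import numpy as np
import pytest

from ancombc.data_model import (AbundanceTable, GroupDesign, TaxonResult,
                                ValidationError, align,
                                empirical_sampling_fraction, microbial_load,
                                read_counts, read_metadata, read_results,
                                write_counts, write_results)


class TestAbundanceTable:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValidationError, match="negative"):
            AbundanceTable(np.array([[1, -1], [2, 3]]), ["a", "b"], ["s1", "s2"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="OTU1"):
            AbundanceTable(np.ones((2, 2)), ["OTU1", "OTU1"], ["s1", "s2"])
        with pytest.raises(ValidationError, match="s1"):
            AbundanceTable(np.ones((2, 2)), ["a", "b"], ["s1", "s1"])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            AbundanceTable(np.ones((2, 3)), ["a", "b"], ["s1", "s2"])

    def test_library_sizes_are_column_sums(self, tiny_table):
        np.testing.assert_array_equal(tiny_table.library_sizes(),
                                      [15, 12, 15, 32, 33])


class TestGroupDesign:
    def test_labels_ordered_by_first_appearance(self):
        d = GroupDesign({"s1": "B", "s2": "A", "s3": "B", "s4": "A"})
        assert d.group_labels == ["B", "A"]
        assert d.reference == "B"
        assert d.sizes() == {"B": 2, "A": 2}

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            GroupDesign({"s1": "A", "s2": "A", "s3": "B"})

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            GroupDesign({"s1": "A", "s2": "A"})


class TestCountsIO:
    def test_round_trip_identity(self, tmp_path, tiny_table):
        path = tmp_path / "counts.tsv"
        write_counts(tiny_table, str(path))
        back = read_counts(str(path))
        assert back.taxon_ids == tiny_table.taxon_ids
        assert back.sample_ids == tiny_table.sample_ids
        np.testing.assert_array_equal(back.counts, tiny_table.counts)

    def test_csv_dialect_inferred_from_suffix(self, tmp_path, tiny_table):
        path = tmp_path / "counts.csv"
        write_counts(tiny_table, str(path))
        back = read_counts(str(path))
        np.testing.assert_array_equal(back.counts, tiny_table.counts)

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ts2\nOTU1\t5\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_counts(str(path))

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ts2\nOTU1\t5\t1.5\n")
        with pytest.raises(ValidationError, match="non-integer"):
            read_counts(str(path))

    def test_duplicate_taxon_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon_id\ts1\nOTU1\t5\nOTU1\t2\n")
        with pytest.raises(ValidationError, match="OTU1"):
            read_counts(str(path))


class TestMetadataIO:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "sample_id\tcountry\n"
            "s1\tMW\ns2\tMW\ns3\tMW\ns4\tVE\ns5\tVE\n"
        )
        d = read_metadata(str(path), "country")
        assert d.group_labels == ["MW", "VE"]
        assert d.sizes() == {"MW": 3, "VE": 2}

    def test_degenerate_group_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tg\ns1\tA\ns2\tA\ns3\tB\n")
        with pytest.raises(ValidationError, match="variance"):
            read_metadata(str(path), "g")

    def test_missing_column_names_available(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tgroup\ns1\tA\ns2\tB\n")
        with pytest.raises(ValidationError, match="group"):
            read_metadata(str(path), "country")

    def test_missing_cell_excluded_with_warning(self, tmp_path, caplog):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tg\ns1\tA\ns2\tA\ns3\t\ns4\tB\ns5\tB\n")
        d = read_metadata(str(path), "g")
        assert "s3" not in d.assignment
        with pytest.raises(ValidationError):
            read_metadata(str(path), "g", strict=True)


class TestAlign:
    def test_identity_when_ids_match(self, tiny_table, tiny_design):
        t, d = align(tiny_table, tiny_design)
        np.testing.assert_array_equal(t.counts, tiny_table.counts)
        assert d.assignment == tiny_design.assignment

    def test_intersect_drops_extra_column(self, tiny_table):
        design = GroupDesign({"s1": "A", "s2": "A", "s3": "A", "s4": "B",
                              "s5": "B", "s6": "B"})
        t, d = align(tiny_table, design)
        assert "s6" not in d.assignment
        assert t.sample_ids == tiny_table.sample_ids

    def test_strict_mismatch_errors(self, tiny_table):
        design = GroupDesign({"s1": "A", "s2": "A", "s4": "B", "s5": "B"})
        with pytest.raises(ValidationError):
            align(tiny_table, design, policy="strict")

    def test_disjoint_ids_error(self, tiny_table):
        design = GroupDesign({"x1": "A", "x2": "A", "x3": "B", "x4": "B"})
        with pytest.raises(ValidationError, match="no shared"):
            align(tiny_table, design)

    def test_idempotent(self, tiny_table, tiny_design):
        t1, d1 = align(tiny_table, tiny_design)
        t2, d2 = align(t1, d1)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        assert d1.assignment == d2.assignment


class TestResultsIO:
    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results([], str(path), group_labels=["A", "B"])
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("taxon_id\teffect")

    def test_structural_zero_row_has_na_statistic(self, tmp_path):
        path = tmp_path / "res.tsv"
        r = TaxonResult("OTU1", p=0.0, p_adj=0.0,
                        structural_zero_flags={"A": True, "B": False},
                        decided_by_structural_zero=True)
        write_results([r], str(path))
        back = read_results(str(path))[0]
        assert np.isnan(back.W)
        assert back.decided_by_structural_zero
        assert back.structural_zero_flags == {"A": True, "B": False}

    def test_round_trip_preserves_12_significant_digits(self, tmp_path):
        rng = np.random.default_rng(3)
        results = []
        for i in range(10):
            e, se = rng.normal(), abs(rng.normal()) + 0.1
            w = e / se
            results.append(TaxonResult(
                f"T{i}", effect=e, se=se, W=w, p=rng.uniform(),
                p_adj=rng.uniform(), ci_lo=e - se, ci_hi=e + se,
                structural_zero_flags={"A": False, "B": bool(i % 2)},
            ))
        path = tmp_path / "res.tsv"
        write_results(results, str(path))
        back = read_results(str(path))
        for orig, rec in zip(results, back):
            for fieldname in ("effect", "se", "W", "p", "p_adj",
                              "ci_lo", "ci_hi"):
                a, b = getattr(orig, fieldname), getattr(rec, fieldname)
                assert b == pytest.approx(a, rel=1e-12)
            assert rec.structural_zero_flags == orig.structural_zero_flags


class TestSamplingFraction:
    def test_toy_two_taxon_example(self):
        # ecosystem A: 12 + 6 organisms, specimen 4 + 2 reads; ecosystem B:
        # 18 + 9 organisms, same specimen counts.
        load_a = microbial_load([12, 6])
        load_b = microbial_load([18, 9])
        assert load_a == 18 and load_b == 27
        assert empirical_sampling_fraction(6, load_a) == pytest.approx(3 / 9)
        assert empirical_sampling_fraction(6, load_b) == pytest.approx(2 / 9)

    def test_zero_load_rejected(self):
        with pytest.raises(ValueError):
            empirical_sampling_fraction(6, 0)
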