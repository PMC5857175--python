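import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from absquant.tables import (
    MINOR_LABEL,
    FeatureTable,
    ParseError,
    RelativeAbundanceTable,
    TaxonLineage,
    ValidationError,
    aggregate_by_rank,
    pool_minor,
    read_feature_table,
    to_relative,
    write_feature_table,
)
from conftest import lineage, random_feature_table


class TestTaxonLineage:
    def test_parses_silva_prefixes_and_truncates_at_unclassified(self):
        lin = TaxonLineage.from_string(
            "d__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__;g__"
        )
        assert lin.at_rank("phylum") == "Firmicutes"
        assert lin.at_rank("family") is None
        assert lin.display_name == "Bacillales"

    def test_plain_semicolon_lineage(self):
        lin = TaxonLineage.from_string("Bacteria;Proteobacteria")
        assert lin.names[:2] == ("Bacteria", "Proteobacteria")
        assert lin.to_string() == "Bacteria;Proteobacteria"

    def test_gap_in_middle_rejected(self):
        with pytest.raises(ValidationError):
            TaxonLineage(("Bacteria", None, "Bacilli", None, None, None))

    def test_unknown_rank_raises(self):
        with pytest.raises(KeyError):
            TaxonLineage.from_string("Bacteria").at_rank("species")


class TestRoundTrip:
    def test_tsv_round_trip_is_identical(self, small_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_feature_table(small_table, path)
        back = read_feature_table(path)
        assert back.samples == small_table.samples
        assert np.array_equal(back.counts, small_table.counts)
        assert [t.to_string() for t in back.taxa] == [
            t.to_string() for t in small_table.taxa
        ]

    def test_biom_equals_tsv(self, small_table, tmp_path):
        """The same matrix through BIOM v1 and TSV yields equal tables."""
        tsv, biom = tmp_path / "t.tsv", tmp_path / "t.biom"
        write_feature_table(small_table, tsv)
        write_feature_table(small_table, biom)
        a, b = read_feature_table(tsv), read_feature_table(biom)
        assert a.samples == b.samples
        assert np.array_equal(a.counts, b.counts)

    def test_dense_biom_read(self, tmp_path):
        doc = {
            "rows": [{"id": "Bacteria;P1;C;O;F;G1", "metadata": None},
                     {"id": "Bacteria;P2;C;O;F;G2", "metadata": None}],
            "columns": [{"id": "A", "metadata": None}, {"id": "B", "metadata": None}],
            "shape": [2, 2],
            "matrix_type": "dense",
            "data": [[2, 3], [5, 0]],
        }
        import json

        path = tmp_path / "d.biom"
        path.write_text(json.dumps(doc))
        table = read_feature_table(path)
        assert np.array_equal(table.counts, [[2, 5], [3, 0]])

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\tS1\nBacteria;P;C;O;F;G\t-1\n")
        with pytest.raises(ValidationError):
            read_feature_table(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("just-one-column\nBacteria\t3\n")
        with pytest.raises(ParseError, match="line 1"):
            read_feature_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\tS1\nBacteria;P;C;O;F;G\t2.5\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_feature_table(path)


class TestToRelative:
    def test_simple_proportions(self):
        table = FeatureTable(
            ("S",), (lineage("B", "P", "C", "O", "F", "G1"),
                     lineage("B", "P", "C", "O", "F", "G2"),
                     lineage("B", "P", "C", "O", "F", "G3")),
            np.array([[2, 3, 5]]),
        )
        rel = to_relative(table)
        assert np.allclose(rel.proportions, [[0.2, 0.3, 0.5]])

    def test_single_taxon_is_one(self):
        table = FeatureTable(("S",), (lineage("B", "P", "C", "O", "F", "G"),),
                             np.array([[42]]))
        assert to_relative(table).proportions[0, 0] == 1.0

    def test_five_reads_at_full_depth(self):
        """5 reads of 66,460 is a proportion of 7.523e-5."""
        table = FeatureTable(
            ("S",), (lineage("B", "P", "C", "O", "F", "G1"),
                     lineage("B", "P", "C", "O", "F", "G2")),
            np.array([[5, 66455]]),
        )
        p = to_relative(table).proportions[0, 0]
        assert p == pytest.approx(7.523e-5, rel=1e-3)

    def test_zero_total_sample_named(self, small_table):
        counts = small_table.counts.copy()
        counts[1] = 0
        table = FeatureTable(small_table.samples, small_table.taxa, counts)
        with pytest.raises(ValidationError, match="S2"):
            to_relative(table)

    @given(
        counts=arrays(np.int64, (3, 8), elements=st.integers(0, 10_000)),
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one(self, counts):
        counts = counts.copy()
        counts[:, 0] += 1
        taxa = tuple(lineage("B", "P", "C", "O", "F", f"G{i}") for i in range(8))
        table = FeatureTable(("A", "B", "C"), taxa, counts)
        sums = to_relative(table).proportions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestAggregateByRank:
    def test_two_genera_one_phylum(self):
        taxa = (lineage("B", "Pr", "C", "O", "F", "G1"),
                lineage("B", "Pr", "C", "O", "F", "G2"),
                lineage("B", "Fi", "C", "O", "F", "G3"))
        rel = RelativeAbundanceTable(("S",), taxa, np.array([[0.2, 0.3, 0.5]]))
        agg = aggregate_by_rank(rel, "phylum")
        names = [t.display_name for t in agg.taxa]
        assert agg.proportions[0, names.index("Pr")] == pytest.approx(0.5)

    def test_genus_aggregation_is_idempotent(self, small_table):
        once = aggregate_by_rank(small_table, "genus")
        twice = aggregate_by_rank(once, "genus")
        assert np.array_equal(once.counts, twice.counts)
        assert [t.to_string() for t in once.taxa] == [
            t.to_string() for t in twice.taxa
        ]

    def test_matches_brute_force_group_sums(self, rng):
        table = random_feature_table(rng, n_samples=3, n_taxa=20)
        agg = aggregate_by_rank(table, "phylum")
        # brute force: dict accumulation per sample
        for i in range(len(table.samples)):
            expected = {}
            for j, taxon in enumerate(table.taxa):
                expected.setdefault(taxon.at_rank("phylum"), 0)
                expected[taxon.at_rank("phylum")] += table.counts[i, j]
            got = {
                t.at_rank("phylum"): agg.counts[i, j]
                for j, t in enumerate(agg.taxa)
            }
            assert got == expected

    def test_conserves_totals(self, rng):
        table = random_feature_table(rng)
        for rank in ("domain", "class", "family"):
            agg = aggregate_by_rank(table, rank)
            assert np.array_equal(agg.sample_totals, table.sample_totals)

    def test_unclassified_at_rank_pooled_under_sentinel(self):
        taxa = (lineage("B", "Pr", "C", "O", "F", "G1"),
                lineage("B"),  # unclassified below domain
                lineage("B", "Fi"))  # unclassified below phylum
        table = FeatureTable(("S",), taxa, np.array([[1, 2, 4]]))
        agg = aggregate_by_rank(table, "genus")
        by_name = {t.display_name: agg.counts[0, j] for j, t in enumerate(agg.taxa)}
        assert by_name["unclassified"] == 6

    def test_unknown_rank_raises(self, small_table):
        with pytest.raises(KeyError):
            aggregate_by_rank(small_table, "species")


class TestPoolMinor:
    def _rel(self, props):
        props = np.asarray(props, dtype=float)
        taxa = tuple(
            lineage("B", "P", "C", "O", "F", f"G{i}")
            for i in range(props.shape[1])
        )
        samples = tuple(f"S{i}" for i in range(props.shape[0]))
        return RelativeAbundanceTable(samples, taxa, props)

    def test_taxon_below_threshold_everywhere_is_pooled(self):
        rel = self._rel([[0.0005, 0.9995], [0.0005, 0.9995]])
        pooled = pool_minor(rel)
        names = [t.display_name for t in pooled.taxa]
        assert MINOR_LABEL in names and "G0" not in names

    def test_taxon_abundant_in_one_sample_is_kept_everywhere(self):
        rel = self._rel([[0.0005, 0.9995], [0.05, 0.95]])
        pooled = pool_minor(rel)
        assert "G0" in [t.display_name for t in pooled.taxa]
        assert MINOR_LABEL not in [t.display_name for t in pooled.taxa]

    def test_exactly_at_threshold_is_retained(self):
        rel = self._rel([[0.001, 0.999]])
        pooled = pool_minor(rel, threshold=0.001)
        assert MINOR_LABEL not in [t.display_name for t in pooled.taxa]

    def test_conserves_sums_and_never_grows(self, rng):
        table = random_feature_table(rng, n_samples=3, n_taxa=30, max_count=20)
        rel = to_relative(table)
        pooled = pool_minor(rel, threshold=0.02)
        assert len(pooled.taxa) <= len(rel.taxa)
        assert np.allclose(
            pooled.proportions.sum(axis=1), rel.proportions.sum(axis=1), atol=1e-12
        )

    def test_bad_threshold_rejected(self, rng):
        rel = to_relative(random_feature_table(rng))
        with pytest.raises(ValueError):
            pool_minor(rel, threshold=0.0)
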