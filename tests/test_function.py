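import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermopath as tp
from thermopath.errors import SampleLookupError
from thermopath.io import Pathway, PathwayCatalog


class TestDetectedTaxa:
    def test_threshold_zero_includes_all_present(self, small_counts_table):
        taxa = tp.detected_taxa(small_counts_table, "A", 0.0)
        # otu1+otu2 collapse to one genus; otu3 absent in A
        assert taxa == ["g__rhodococcus", "g__bacillus"]

    def test_threshold_filters(self, small_counts_table):
        assert tp.detected_taxa(small_counts_table, "A", 0.5) == ["g__rhodococcus"]

    def test_unknown_sample(self, small_counts_table):
        with pytest.raises(SampleLookupError):
            tp.detected_taxa(small_counts_table, "nope", 0.0)


class TestSampleKoSet:
    def test_union(self, tiny_db):
        kos, report = tp.sample_ko_set(
            ["g__rhodococcus", "g__pseudomonas"], tiny_db, rank_fallback=False
        )
        assert kos == frozenset({"K00001", "K00002", "K00003"})
        assert report.unmatched == []

    def test_unmatched_contributes_nothing(self, tiny_db):
        kos, report = tp.sample_ko_set(
            ["g__rhodococcus", "g__unknownium"], tiny_db, rank_fallback=False
        )
        assert kos == frozenset({"K00001", "K00002"})
        assert report.unmatched == ["g__unknownium"]

    def test_species_falls_back_to_genus(self, tiny_db):
        lin = tp.Lineage.parse("k__Bacteria; g__Rhodococcus; s__ruber")
        lookup = {"s__ruber": lin}.get
        kos, report = tp.sample_ko_set(
            ["s__ruber"], tiny_db, rank_fallback=True, taxonomy_lookup=lookup
        )
        assert kos == frozenset({"K00001", "K00002"})
        assert report.fallback == [("s__ruber", "g__rhodococcus")]

    def test_superset_community_has_superset_kos(self, tiny_db):
        kos_small, _ = tp.sample_ko_set(["g__rhodococcus"], tiny_db)
        kos_big, _ = tp.sample_ko_set(["g__rhodococcus", "g__pseudomonas"], tiny_db)
        assert kos_big >= kos_small


@pytest.mark.parametrize(
    "kos, pathway_kos, expected",
    [
        ({"K00001", "K00003"}, {"K00001", "K00002", "K00003", "K00004"}, 0.5),
        ({"K00009"}, {"K00001", "K00002"}, 0.0),
        ({"K00001", "K00002", "K00003"}, {"K00001", "K00002"}, 1.0),
    ],
)
def test_pathway_completeness_ratio(kos, pathway_kos, expected):
    pathway = Pathway("p", "P", frozenset(pathway_kos))
    assert tp.pathway_completeness(frozenset(kos), pathway) == expected


class TestCompletenessMatrix:
    def test_single_sample_example(self):
        table = tp.OtuTable(
            data=pd.DataFrame([[7.0]], index=["s1"], columns=["otu1"]),
            unit="counts",
            taxonomy={"otu1": tp.Lineage.parse("k__Bacteria; g__Alpha")},
        )
        db = tp.AnnotationDB({"g__alpha": frozenset({"K00001"})})
        catalog = PathwayCatalog(
            (
                Pathway("P1", "one", frozenset({"K00001"})),
                Pathway("P2", "two", frozenset({"K00001", "K00002"})),
            )
        )
        cm = tp.completeness_matrix(table, db, catalog)
        assert cm.data.loc["s1"].tolist() == [1.0, 0.5]
        assert cm.ko_set_sizes["s1"] == 1

    def test_unmatched_sample_gives_zero_row(self, tiny_catalog):
        table = tp.OtuTable(
            data=pd.DataFrame([[5.0]], index=["s1"], columns=["otuX"]),
            unit="counts",
            taxonomy={"otuX": tp.Lineage.parse("k__Bacteria; g__Nowhere")},
        )
        db = tp.AnnotationDB({"g__elsewhere": frozenset({"K00001"})})
        cm = tp.completeness_matrix(table, db, tiny_catalog)
        assert (cm.data.loc["s1"] == 0.0).all()
        assert cm.match_reports["s1"].unmatched == ["g__nowhere"]

    def test_adding_taxon_never_decreases_row(self, tiny_db, tiny_catalog):
        base = tp.OtuTable(
            data=pd.DataFrame([[5.0, 0.0]], index=["s"], columns=["o1", "o2"]),
            unit="counts",
            taxonomy={
                "o1": tp.Lineage.parse("k__Bacteria; g__Rhodococcus"),
                "o2": tp.Lineage.parse("k__Bacteria; g__Pseudomonas"),
            },
        )
        more = tp.OtuTable(
            data=pd.DataFrame([[5.0, 5.0]], index=["s"], columns=["o1", "o2"]),
            unit="counts", taxonomy=base.taxonomy,
        )
        row0 = tp.completeness_matrix(base, tiny_db, tiny_catalog).data.loc["s"]
        row1 = tp.completeness_matrix(more, tiny_db, tiny_catalog).data.loc["s"]
        assert (row1 >= row0).all()

    def test_invariant_to_input_row_and_column_order(self, coupled_dataset):
        ds = coupled_dataset
        sub = ds.otu_table.data.iloc[:4, :50]
        tax = {o: ds.otu_table.taxonomy[o] for o in sub.columns}
        t1 = tp.OtuTable(data=sub, unit="counts", taxonomy=tax)
        shuffled = sub.iloc[::-1, ::-1]
        t2 = tp.OtuTable(data=shuffled, unit="counts", taxonomy=tax)
        m1 = tp.completeness_matrix(t1, ds.annotations, ds.catalog).data
        m2 = tp.completeness_matrix(t2, ds.annotations, ds.catalog).data
        pd.testing.assert_frame_equal(m1.sort_index(), m2.sort_index())


def brute_force_completeness(taxa_kos: list[set], catalog: PathwayCatalog) -> list[float]:
    """Set-enumeration oracle: explicit loops, no set algebra shortcuts."""
    detected = set()
    for kos in taxa_kos:
        for ko in kos:
            detected.add(ko)
    out = []
    for pathway in catalog:
        hits = 0
        for ko in pathway.kos:
            if ko in detected:
                hits += 1
        out.append(hits / len(pathway.kos))
    return out


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_brute_force_oracle_on_small_catalogs(data):
    """Random catalogs up to 5 pathways x 10 KOs match the enumeration oracle."""
    ko_pool = [f"K{i:05d}" for i in range(1, 11)]
    n_path = data.draw(st.integers(1, 5))
    catalog = PathwayCatalog(
        tuple(
            Pathway(
                f"p{i}", f"P{i}",
                frozenset(data.draw(st.sets(st.sampled_from(ko_pool), min_size=1))),
            )
            for i in range(n_path)
        )
    )
    n_taxa = data.draw(st.integers(1, 4))
    taxa_kos = [
        set(data.draw(st.sets(st.sampled_from(ko_pool), min_size=1)))
        for _ in range(n_taxa)
    ]
    table = tp.OtuTable(
        data=pd.DataFrame([[1.0] * n_taxa], index=["s"],
                          columns=[f"o{i}" for i in range(n_taxa)]),
        unit="counts",
        taxonomy={
            f"o{i}": tp.Lineage.parse(f"k__Bacteria; g__Genus{i}") for i in range(n_taxa)
        },
    )
    db = tp.AnnotationDB(
        {f"g__genus{i}": frozenset(taxa_kos[i]) for i in range(n_taxa)}
    )
    cm = tp.completeness_matrix(table, db, catalog)
    expected = brute_force_completeness(taxa_kos, catalog)
    assert cm.data.loc["s"].tolist() == expected


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_completeness_values_are_exact_rationals(data):
    ko_pool = [f"K{i:05d}" for i in range(1, 11)]
    pathway_kos = data.draw(st.sets(st.sampled_from(ko_pool), min_size=1))
    kos = frozenset(data.draw(st.sets(st.sampled_from(ko_pool))))
    pathway = Pathway("p", "P", frozenset(pathway_kos))
    value = tp.pathway_completeness(kos, pathway)
    n = len(pathway_kos)
    assert value * n == int(round(value * n))  # numerator is an integer
    assert 0.0 <= value <= 1.0


class TestHighCompleteness:
    def _matrix(self, values, pathways):
        data = pd.DataFrame(values, columns=pathways,
                            index=[f"s{i}" for i in range(len(values))])
        return tp.CompletenessMatrix(data=data, ko_set_sizes=pd.Series(dtype=int),
                                     match_reports={})

    def test_boundary_mean_included(self):
        cm = self._matrix([[1.0], [0.8]], ["P1"])
        out = tp.high_completeness_pathways(cm, threshold=0.9, aggregate="mean")
        assert list(out.index) == ["P1"]
        assert out.loc["P1", "completeness"] == pytest.approx(0.9)

    def test_min_aggregate_excludes(self):
        cm = self._matrix([[1.0], [0.8]], ["P1"])
        out = tp.high_completeness_pathways(cm, threshold=0.9, aggregate="min")
        assert len(out) == 0

    def test_threshold_one_only_universal(self):
        cm = self._matrix([[1.0, 1.0], [1.0, 0.99]], ["P1", "P2"])
        out = tp.high_completeness_pathways(cm, threshold=1.0)
        assert list(out.index) == ["P1"]

    def test_sorted_descending_then_by_id(self):
        cm = self._matrix([[0.95, 0.99, 0.95]], ["Pb", "Pa", "Pa0"])
        out = tp.high_completeness_pathways(cm, threshold=0.9)
        assert list(out.index) == ["Pa", "Pa0", "Pb"]
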