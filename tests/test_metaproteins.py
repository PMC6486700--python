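"""UniRef50 grouping, spectral counting, LCA and function merging."""

import io
import random

import pytest

from metaprofiler.metaproteins import (
    ProteinAnnotation,
    assign_lca,
    build_metaproteins,
    group_by_uniref,
    read_annotation_table,
    summarize_function,
    write_annotation_table,
)

from conftest import make_record, make_set

BP = "Biological process"


def ann(accession, uniref=None, tax_id=None, keywords=(), ec=(), ko=(), desc=""):
    return ProteinAnnotation(
        accession=accession,
        uniref50_id=uniref,
        tax_id=tax_id,
        keywords=frozenset(keywords),
        ec_numbers=frozenset(ec),
        ko_ids=frozenset(ko),
        description=desc,
    )


@pytest.fixture
def annotations():
    return {
        "P1": ann("P1", "UniRef50_U1", 13, [(BP, "Transport")], desc="B protein"),
        "P2": ann("P2", "UniRef50_U1", 16, [(BP, "Methanogenesis")], desc="A protein"),
        "P3": ann("P3", "UniRef50_U2", 33),
        "P4": ann("P4", None, 13),
    }


class TestGrouping:
    def test_shared_uniref_counts_both_spectra(self, annotations):
        results = make_set(
            [
                make_record("s1", accessions=("P1",)),
                make_record("s2", accessions=("P2",)),
            ]
        )
        groups = group_by_uniref(results, annotations)
        assert len(groups) == 1
        assert groups[0].group_id == "UniRef50_U1"
        assert groups[0].spectral_counts == {"A": 2}

    def test_one_spectrum_two_groups_counts_once_each(self, annotations):
        results = make_set([make_record("s1", accessions=("P1", "P3"))])
        groups = group_by_uniref(results, annotations)
        by_id = {g.group_id: g for g in groups}
        assert by_id["UniRef50_U1"].spectral_counts == {"A": 1}
        assert by_id["UniRef50_U2"].spectral_counts == {"A": 1}
        assert len(results.distinct_spectra()) == 1

    def test_same_group_never_counts_a_spectrum_twice(self, annotations):
        results = make_set([make_record("s1", accessions=("P1", "P2"))])
        groups = group_by_uniref(results, annotations)
        assert groups[0].spectral_counts == {"A": 1}

    def test_unclustered_accession_gets_singleton(self, annotations):
        results = make_set([make_record("s1", accessions=("P4",))])
        groups = group_by_uniref(results, annotations)
        assert groups[0].group_id == "SINGLETON:P4"

    def test_unannotated_record_warns_and_survives(self, annotations):
        results = make_set([make_record("s1", accessions=("PX",))])
        with pytest.warns(UserWarning, match="singleton"):
            groups = group_by_uniref(results, annotations)
        assert groups[0].group_id == "SINGLETON:PX"

    def test_order_invariance(self, annotations):
        records = [
            make_record(f"s{i}", accessions=("P1",) if i % 2 else ("P2", "P3"))
            for i in range(20)
        ]
        shuffled = records[:]
        random.Random(4).shuffle(shuffled)
        a = group_by_uniref(make_set(records), annotations)
        b = group_by_uniref(make_set(shuffled), annotations)
        assert [(g.group_id, g.spectral_counts) for g in a] == [
            (g.group_id, g.spectral_counts) for g in b
        ]

    def test_every_accession_in_exactly_one_group(self, annotations):
        records = [
            make_record(f"s{i}", accessions=accs)
            for i, accs in enumerate([("P1",), ("P2", "P3"), ("P4",)])
        ]
        groups = group_by_uniref(make_set(records), annotations)
        seen = [a for g in groups for a in g.member_accessions]
        assert sorted(seen) == sorted(set(seen))

    def test_spectrum_support_conservation(self, annotations):
        # no shared spectra across groups -> equality; shared -> inequality
        exclusive = make_set(
            [make_record("s1", accessions=("P1",)),
             make_record("s2", accessions=("P3",))]
        )
        groups = group_by_uniref(exclusive, annotations)
        assert sum(g.total_spectra for g in groups) == len(
            exclusive.distinct_spectra()
        )
        shared = make_set([make_record("s1", accessions=("P1", "P3"))])
        groups = group_by_uniref(shared, annotations)
        assert sum(g.total_spectra for g in groups) >= len(
            shared.distinct_spectra()
        )


class TestLcaAssignment:
    def test_single_species_members(self, annotations, small_tree):
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("P3",))]), annotations
        )
        assert assign_lca(groups[0], annotations, small_tree).lca_tax_id == 33

    def test_two_families_resolve_to_order(self, annotations, small_tree):
        # P1 at Bacillus subtilis (13), P2 at Paenibacillus polymyxa (16)
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("P1",)),
                      make_record("s2", accessions=("P2",))]),
            annotations,
        )
        assert assign_lca(groups[0], annotations, small_tree).lca_tax_id == 10

    def test_no_taxa_means_root(self, small_tree):
        table = {"PX": ann("PX", "UniRef50_U9")}
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("PX",))]), table
        )
        assert assign_lca(groups[0], table, small_tree).lca_tax_id == small_tree.root_id

    def test_tax_id_missing_from_tree_warns(self, small_tree):
        table = {"PX": ann("PX", "UniRef50_U9", tax_id=424242)}
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("PX",))]), table
        )
        with pytest.warns(UserWarning, match="424242"):
            assign_lca(groups[0], table, small_tree)
        assert groups[0].lca_tax_id == small_tree.root_id


class TestFunctionSummary:
    def test_keywords_unioned_and_description_tiebreak(self, annotations):
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("P1",)),
                      make_record("s2", accessions=("P2",))]),
            annotations,
        )
        mp = summarize_function(groups[0], annotations)
        assert mp.biological_processes == {"Transport", "Methanogenesis"}
        assert mp.description == "A protein"  # lexicographically smallest

    def test_empty_annotation_sets_stay_empty(self, annotations):
        groups = group_by_uniref(
            make_set([make_record("s1", accessions=("P3",))]), annotations
        )
        mp = summarize_function(groups[0], annotations)
        assert mp.biological_processes == set()
        assert mp.ec_numbers == set()


class TestAnnotationIo:
    def test_round_trip(self, annotations):
        buffer = io.StringIO()
        write_annotation_table(annotations, buffer)
        buffer.seek(0)
        again = read_annotation_table(buffer)
        assert again == annotations

    def test_category_tagged_keywords_parse(self):
        text = (
            "accession\tuniref50_id\ttax_id\tkeywords\tec\tko\tdescription\n"
            "P1\tUniRef50_X\t13\tBiological process:Transport;Ligand:Zinc\t"
            "1.1.1.1\tK00001\tSome protein\n"
        )
        table = read_annotation_table(io.StringIO(text))
        assert table["P1"].keywords == frozenset(
            {("Biological process", "Transport"), ("Ligand", "Zinc")}
        )

    def test_build_metaproteins_end_to_end(self, annotations, small_tree):
        results = make_set(
            [make_record("s1", accessions=("P1",)),
             make_record("s2", accessions=("P2",)),
             make_record("s3", sample_id="B", accessions=("P3",))]
        )
        mps = build_metaproteins(results, annotations, small_tree)
        by_id = {m.group_id: m for m in mps}
        assert by_id["UniRef50_U1"].lca_tax_id == 10
        assert by_id["UniRef50_U2"].spectral_counts == {"B": 1}
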