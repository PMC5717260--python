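"""Functional-alteration filtering, node-status projection, DWN deduplication."""

import pandas as pd
import pytest

from netdyn.genomics import (
    FilterConfig,
    GeneMap,
    GenomicsValidationError,
    build_dwns,
    filter_functional_alterations,
    project_to_node_status,
    topology_subgroup,
)
from netdyn.network import NodeStatusProfile


def mut(cell_line, gene, variant_class, impact="na", gene_role="na"):
    return dict(cell_line=cell_line, gene=gene, variant_class=variant_class,
                impact=impact, gene_role=gene_role)


def cna(cell_line, gene, call, mrna_z):
    return dict(cell_line=cell_line, gene=gene, call=call, mrna_z=mrna_z)


def frame(rows):
    return pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["cell_line", "gene", "variant_class", "impact", "gene_role"]
    )


EMPTY_CNA = pd.DataFrame(columns=["cell_line", "gene", "call", "mrna_z"])
EMPTY_MUT = frame([])


class TestFilter:
    @pytest.mark.parametrize(
        "record,expected_call",
        [
            (mut("c1", "G", "missense", "high", "oncogene"), "MUT_A"),
            (mut("c1", "G", "missense", "medium", "tumor_suppressor"), "MUT_I"),
            (mut("c1", "G", "nonsense"), "MUT_I"),
            (mut("c1", "G", "frameshift"), "MUT_I"),
        ],
    )
    def test_functional_mutations_kept(self, record, expected_call):
        calls = filter_functional_alterations(frame([record]), EMPTY_CNA)
        assert calls["call"].tolist() == [expected_call]

    @pytest.mark.parametrize(
        "record",
        [
            mut("c1", "G", "silent"),
            mut("c1", "G", "rna"),
            mut("c1", "G", "intron"),
            mut("c1", "G", "utr"),
            mut("c1", "G", "flank"),
            mut("c1", "G", "intergenic"),
            mut("c1", "G", "missense", "low", "oncogene"),
            mut("c1", "G", "missense", "neutral", "tumor_suppressor"),
            mut("c1", "G", "missense", "high", "na"),  # no curated role: dropped
        ],
    )
    def test_nonfunctional_mutations_excluded(self, record):
        assert filter_functional_alterations(frame([record]), EMPTY_CNA).empty

    @pytest.mark.parametrize(
        "call,z,expected",
        [
            ("AMP", 2.0, "CNA_A"),
            ("GAIN", 1.0, "CNA_A"),
            ("HOMDEL", -2.0, "CNA_I"),
            ("LOSS", -1.5, "CNA_I"),
        ],
    )
    def test_concordant_cnas_kept(self, call, z, expected):
        calls = filter_functional_alterations(EMPTY_MUT, pd.DataFrame([cna("c1", "G", call, z)]))
        assert calls["call"].tolist() == [expected]

    @pytest.mark.parametrize(
        "call,z",
        [
            ("AMP", 0.1),      # discordant at t=1
            ("GAIN", -2.0),    # wrong direction
            ("HOMDEL", 0.0),
            ("LOSS", 2.0),
            ("DIPLOID", 3.0),  # no copy-number change
        ],
    )
    def test_discordant_cnas_excluded(self, call, z):
        assert filter_functional_alterations(EMPTY_MUT, pd.DataFrame([cna("c1", "G", call, z)])).empty

    def test_concordance_threshold_is_configurable(self):
        table = pd.DataFrame([cna("c1", "G", "AMP", 0.8)])
        assert filter_functional_alterations(EMPTY_MUT, table).empty
        kept = filter_functional_alterations(EMPTY_MUT, table, FilterConfig(concordance_z=0.5))
        assert kept["call"].tolist() == ["CNA_A"]

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(GenomicsValidationError):
            filter_functional_alterations(frame([mut("c1", "G", "splice_site")]), EMPTY_CNA)
        with pytest.raises(GenomicsValidationError):
            filter_functional_alterations(EMPTY_MUT, pd.DataFrame([cna("c1", "G", "DEL", -2)]))

    def test_order_independent_and_idempotent_selection(self):
        rows = [
            mut("c2", "G1", "missense", "high", "oncogene"),
            mut("c1", "G2", "nonsense"),
            mut("c1", "G3", "silent"),
        ]
        a = filter_functional_alterations(frame(rows), EMPTY_CNA)
        b = filter_functional_alterations(frame(rows[::-1]), EMPTY_CNA)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["call"]) == {"MUT_A", "MUT_I"}


class TestProjection:
    def test_single_call_projects_to_node(self, ref_net):
        calls = filter_functional_alterations(
            EMPTY_MUT, pd.DataFrame([cna("c1", "AKT1", "AMP", 2.0)])
        )
        profiles = project_to_node_status(calls, {"AKT": {"AKT1", "AKT2"}}, ref_net)
        assert profiles["c1"].profile["AKT"] == "A"
        assert profiles["c1"].n_alterations == 1

    def test_no_calls_gives_all_n_profile(self, ref_net):
        calls = filter_functional_alterations(EMPTY_MUT, EMPTY_CNA)
        profiles = project_to_node_status(calls, {}, ref_net, cell_lines=["c1"])
        assert profiles["c1"].n_alterations == 0

    def test_mutation_evidence_outranks_cna(self, ref_net):
        table = pd.DataFrame(
            [
                dict(cell_line="c1", gene="TP53BP_x", call="MUT_I", evidence="mutation"),
                dict(cell_line="c1", gene="GeneY", call="CNA_A", evidence="cna"),
            ]
        )
        profiles = project_to_node_status(table, {"Wip1": {"TP53BP_x", "GeneY"}}, ref_net)
        assert profiles["c1"].profile["Wip1"] == "I"

    def test_mutation_level_conflict_is_an_error(self, ref_net):
        table = pd.DataFrame(
            [
                dict(cell_line="c1", gene="Ga", call="MUT_I", evidence="mutation"),
                dict(cell_line="c1", gene="Gb", call="MUT_A", evidence="mutation"),
            ]
        )
        with pytest.raises(GenomicsValidationError, match="conflict"):
            project_to_node_status(table, {"Wip1": {"Ga", "Gb"}}, ref_net)

    def test_unmapped_genes_ignored(self, ref_net):
        table = pd.DataFrame(
            [dict(cell_line="c1", gene="UNMAPPED", call="CNA_A", evidence="cna")]
        )
        profiles = project_to_node_status(table, {"AKT": {"AKT1"}}, ref_net)
        assert profiles["c1"].n_alterations == 0


class TestDwns:
    def test_identical_profiles_merge(self, ref_net, make_profile):
        p1 = NodeStatusProfile(make_profile(ref_net, AKT="A").profile, ("c1",))
        p2 = NodeStatusProfile(make_profile(ref_net, AKT="A").profile, ("c2",))
        dwns = build_dwns([p1, p2])
        assert len(dwns) == 1
        assert dwns[0].member_cell_lines == ("c1", "c2")
        assert dwns[0].dwn_id == "DWN_1_1"

    def test_ids_encode_alteration_count_and_lexicographic_rank(self, ref_net, make_profile):
        profiles = {
            "c1": make_profile(ref_net, AKT="A", Wip1="A", p14ARF="I"),
            "c2": make_profile(ref_net, AKT="A"),
            "c3": make_profile(ref_net, BCL2="A", CyclinE="A", p21="I"),
        }
        dwns = build_dwns(profiles)
        by_id = {d.dwn_id: d for d in dwns}
        assert set(by_id) == {"DWN_1_1", "DWN_3_1", "DWN_3_2"}
        # lexicographic on the signature: AKT:A|... < BCL2:A|...
        assert by_id["DWN_3_1"].altered_nodes == ("AKT", "Wip1", "p14ARF")

    def test_empty_input(self):
        assert build_dwns({}) == []

    def test_partition_property(self, ref_net, make_profile):
        profiles = {
            f"c{i}": make_profile(ref_net, **alts)
            for i, alts in enumerate(
                [{"AKT": "A"}, {"AKT": "A"}, {"Wip1": "I"}, {"AKT": "A", "Wip1": "I"}, {}]
            )
        }
        dwns = build_dwns(profiles)
        members = [m for d in dwns for m in d.member_cell_lines]
        assert sorted(members) == sorted(profiles)  # no line lost or duplicated
        assert len(dwns) <= len(profiles)


class TestSubgroups:
    def test_p14arf_inactivation_takes_precedence(self, ref_net, make_profile):
        assert topology_subgroup(make_profile(ref_net, p14ARF="I", AKT="A")) == 1

    def test_akt_activation_without_p14arf_loss(self, ref_net, make_profile):
        assert topology_subgroup(make_profile(ref_net, AKT="A")) == 3

    def test_fallback_subgroup(self, ref_net, make_profile):
        assert topology_subgroup(make_profile(ref_net)) == 2
        assert topology_subgroup(make_profile(ref_net, BCL2="A")) == 2

    def test_every_profile_gets_exactly_one_subgroup(self, ref_net, make_profile):
        for alts in [{}, {"p14ARF": "A"}, {"AKT": "I"}, {"p14ARF": "I"}, {"AKT": "A", "BCL2": "I"}]:
            assert topology_subgroup(make_profile(ref_net, **alts)) in (1, 2, 3)


def test_gene_map_round_trip():
    gm = GeneMap.parse("AKT: AKT1, AKT2  # kinases\n\nWip1: PPM1D\n")
    assert gm.mapping == {"AKT": {"AKT1", "AKT2"}, "Wip1": {"PPM1D"}}
    assert GeneMap.parse(gm.serialize()).mapping == gm.mapping
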