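"""ADM1 step mapping, taxon restrictions, coverage and methanogenesis typing."""

import io

import pytest

from metaprofiler.adm1 import (
    MIXOTROPHIC,
    STRICTLY_HYDROGENOTROPHIC,
    UNCLASSIFIABLE,
    Adm1ConfigError,
    Adm1Map,
    Adm1Step,
    acds_split,
    classify_methanogenesis,
    coverage_report,
    default_adm1_map,
    load_adm1_map,
    map_to_steps,
)
from metaprofiler.metaproteins import Metaprotein

MAP_TSV = """\
step_id\tstage\tsubstrate\tec\tko\trestriction
hydro_carb\thydrolysis\tcarbohydrate\t3.2.1.4\t\tnone
hydro_lipid\thydrolysis\tlipid\t3.1.1.3\t\tnone
ferm\tacidogenesis/fermentation\tcarbohydrate\t\tK00001\tbacteria_only
meth_h2\tmethanogenesis\tH2/CO2\t\tK00399\tarchaea_only
meth_ac\tmethanogenesis\tacetate\t\tK00925\tarchaea_only
"""


def mp(group_id, lca, counts, ec=(), ko=()):
    m = Metaprotein(group_id=group_id, member_accessions={group_id})
    m.lca_tax_id = lca
    m.spectral_counts = dict(counts)
    m.ec_numbers = set(ec)
    m.ko_ids = set(ko)
    return m


@pytest.fixture
def toy_map():
    return load_adm1_map(io.StringIO(MAP_TSV))


class TestMapLoading:
    def test_default_map_covers_all_stages(self):
        adm1_map = default_adm1_map()
        assert len(adm1_map.stages) >= 5
        assert "methanogenesis" in adm1_map.stages

    def test_step_without_identifiers_rejected(self):
        with pytest.raises(Adm1ConfigError, match="no EC and no KO"):
            Adm1Map(steps=[Adm1Step("x", "hydrolysis", "lipid",
                                    frozenset(), frozenset())])

    def test_duplicate_step_id_rejected(self):
        step = Adm1Step("x", "hydrolysis", "lipid", frozenset({"3.1.1.3"}),
                        frozenset())
        with pytest.raises(Adm1ConfigError, match="duplicate"):
            Adm1Map(steps=[step, step])

    def test_user_supplied_extra_step_present(self, toy_map):
        extra = Adm1Step("custom", "one_carbon", "methyl", frozenset(),
                         frozenset({"K99999"}))
        combined = Adm1Map(steps=toy_map.steps + [extra])
        assert any(s.step_id == "custom" for s in combined.steps)


class TestStepMapping:
    # tax ids from the shared fixture tree: 13 bacterial species,
    # 33 archaeal species
    def test_archaeal_methanogenesis_counted(self, toy_map, small_tree):
        mps = [mp("m1", 33, {"s1": 5}, ko=("K00399",))]
        steps = {s.step_id: s for s in map_to_steps(mps, toy_map, small_tree)}
        assert steps["meth_h2"].counts == {"s1": 5}

    def test_bacterial_same_ko_excluded_by_restriction(self, toy_map, small_tree):
        mps = [mp("m1", 13, {"s1": 5}, ko=("K00399",))]
        steps = {s.step_id: s for s in map_to_steps(mps, toy_map, small_tree)}
        assert steps["meth_h2"].counts == {}

    def test_restriction_never_increases_counts(self, toy_map, small_tree):
        mps = [
            mp("m1", 13, {"s1": 4}, ko=("K00001",)),
            mp("m2", 33, {"s1": 6}, ko=("K00001",)),
        ]
        unrestricted = Adm1Map(steps=[
            Adm1Step(s.step_id, s.stage, s.substrate, s.ec_numbers, s.ko_ids,
                     "none")
            for s in toy_map.steps
        ])
        restricted = {s.step_id: s.total
                      for s in map_to_steps(mps, toy_map, small_tree)}
        free = {s.step_id: s.total
                for s in map_to_steps(mps, unrestricted, small_tree)}
        assert all(restricted[k] <= free[k] for k in restricted)

    def test_four_metaprotein_stage_fractions(self, toy_map, small_tree):
        mps = [
            mp("m1", 13, {"s1": 6}, ec=("3.2.1.4",)),
            mp("m2", 13, {"s1": 2}, ec=("3.1.1.3",)),
            mp("m3", 33, {"s1": 3}, ko=("K00399",)),
            mp("m4", 33, {"s1": 9}, ko=("K00925",)),
        ]
        steps = {s.step_id: s for s in map_to_steps(mps, toy_map, small_tree)}
        assert steps["hydro_carb"].stage_fractions["s1"] == pytest.approx(6 / 8)
        assert steps["hydro_lipid"].stage_fractions["s1"] == pytest.approx(2 / 8)
        assert steps["meth_ac"].stage_fractions["s1"] == pytest.approx(9 / 12)

    def test_stage_fractions_sum_to_one(self, toy_map, small_tree):
        mps = [
            mp("m1", 13, {"s1": 6}, ec=("3.2.1.4",)),
            mp("m2", 13, {"s1": 2}, ec=("3.1.1.3",)),
        ]
        steps = map_to_steps(mps, toy_map, small_tree)
        total = sum(s.stage_fractions.get("s1", 0.0)
                    for s in steps if s.stage == "hydrolysis")
        assert total == pytest.approx(1.0)

    def test_metaprotein_may_match_multiple_steps(self, toy_map, small_tree):
        mps = [mp("m1", 13, {"s1": 5}, ec=("3.2.1.4", "3.1.1.3"))]
        steps = {s.step_id: s.total
                 for s in map_to_steps(mps, toy_map, small_tree)}
        assert steps["hydro_carb"] == 5 and steps["hydro_lipid"] == 5


class TestCoverage:
    def test_missing_lipid_step_flagged_absent(self, toy_map, small_tree):
        mps = [mp("m1", 13, {"s1": 6}, ec=("3.2.1.4",))]
        report = coverage_report(map_to_steps(mps, toy_map, small_tree))
        assert "hydro_lipid" in report["hydrolysis"]["absent"]
        assert "hydro_carb" in report["hydrolysis"]["present"]

    def test_all_zero_input_all_absent(self, toy_map, small_tree):
        report = coverage_report(map_to_steps([], toy_map, small_tree))
        assert all(not v["present"] for v in report.values())

    def test_fully_populated_none_absent(self, toy_map, small_tree):
        mps = [
            mp("m1", 13, {"s1": 1}, ec=("3.2.1.4", "3.1.1.3")),
            mp("m2", 13, {"s1": 1}, ko=("K00001",)),
            mp("m3", 33, {"s1": 1}, ko=("K00399", "K00925")),
        ]
        report = coverage_report(map_to_steps(mps, toy_map, small_tree))
        assert all(not v["absent"] for v in report.values())


class TestMethanogenesisTyping:
    def _calls(self, aceto, hydro, toy_map, tree, theta=0.1):
        mps = [
            mp("h", 33, {"s1": hydro}, ko=("K00399",)),
            mp("a", 33, {"s1": aceto}, ko=("K00925",)),
        ]
        steps = map_to_steps(mps, toy_map, tree)
        return classify_methanogenesis(steps, theta=theta)

    def test_zero_share_is_strictly_hydrogenotrophic(self, toy_map, small_tree):
        (call,) = self._calls(0, 10, toy_map, small_tree)
        assert call.label == STRICTLY_HYDROGENOTROPHIC

    def test_half_share_is_mixotrophic(self, toy_map, small_tree):
        (call,) = self._calls(5, 5, toy_map, small_tree)
        assert call.label == MIXOTROPHIC
        assert call.acetoclastic_share == pytest.approx(0.5)

    def test_zero_methanogenesis_unclassifiable(self, toy_map, small_tree):
        mps = [mp("m1", 13, {"s1": 6}, ec=("3.2.1.4",))]
        (call,) = classify_methanogenesis(map_to_steps(mps, toy_map, small_tree))
        assert call.label == UNCLASSIFIABLE

    @pytest.mark.parametrize("theta", [0.05, 0.1, 0.2, 0.35])
    def test_threshold_sweep_recovers_truth(self, theta, toy_map, small_tree):
        # generator-style communities: mixotrophic ~40% acetoclastic,
        # strictly hydrogenotrophic ~1%
        (mixo,) = self._calls(40, 60, toy_map, small_tree, theta)
        (strict,) = self._calls(1, 99, toy_map, small_tree, theta)
        assert mixo.label == MIXOTROPHIC
        assert strict.label == STRICTLY_HYDROGENOTROPHIC

    def test_acds_split_reported(self, toy_map, small_tree):
        mps = [
            mp("arch", 33, {"s1": 7}, ko=("K00193",)),
            mp("bact", 13, {"s1": 11}, ko=("K00194",)),
            mp("meth", 33, {"s1": 5}, ko=("K00399",)),
        ]
        split = acds_split(mps, small_tree)
        assert split["s1"] == {"archaeal": 7, "bacterial": 11}
        calls = classify_methanogenesis(
            map_to_steps(mps, toy_map, small_tree), split
        )
        assert calls[0].acds_bacterial == 11
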