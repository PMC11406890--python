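import filecmp

import pytest

import weanflux as wf
from weanflux.screening import MissingCompoundError, load_report, load_screen_config
from weanflux.solver import TradeoffSolution

from conftest import make_linear_taxon


def _fake_solution(exchanges):
    return TradeoffSolution(
        mu_c=0.1, mu_c_max=0.1, mu_i={}, alpha=1.0, fluxes={},
        status="optimal", exchanges=exchanges,
    )


class TestAggregation:
    def test_weighted_sum_of_producers(self):
        sol = _fake_solution({("A", "butyrate"): 10.0, ("B", "butyrate"): 5.0})
        profile = wf.AbundanceProfile({"A": 0.6, "B": 0.4})
        assert wf.aggregate_metabolite_flux(sol, profile, "butyrate") == pytest.approx(8.0)

    def test_zero_secretions_aggregate_to_zero(self):
        sol = _fake_solution({("A", "acetate"): 0.0})
        profile = wf.AbundanceProfile({"A": 1.0})
        assert wf.aggregate_metabolite_flux(sol, profile, "acetate") == 0.0

    def test_single_taxon_degenerate_case(self):
        sol = _fake_solution({("A", "acetate"): 3.5})
        profile = wf.AbundanceProfile({"A": 1.0})
        assert wf.aggregate_metabolite_flux(sol, profile, "acetate") == pytest.approx(3.5)

    def test_producers_mode_ignores_consumers_net_mode_subtracts(self):
        sol = _fake_solution({("A", "acetate"): 10.0, ("B", "acetate"): -4.0})
        profile = wf.AbundanceProfile({"A": 0.5, "B": 0.5})
        assert wf.aggregate_metabolite_flux(sol, profile, "acetate") == pytest.approx(5.0)
        assert wf.aggregate_metabolite_flux(
            sol, profile, "acetate", mode="net"
        ) == pytest.approx(3.0)

    def test_unknown_compound_raises(self):
        sol = _fake_solution({("A", "acetate"): 1.0})
        with pytest.raises(MissingCompoundError):
            wf.aggregate_metabolite_flux(sol, wf.AbundanceProfile({"A": 1.0}), "urea")

    def test_aggregation_is_linear_in_secretions(self):
        profile = wf.AbundanceProfile({"A": 0.6, "B": 0.4})
        base = {("A", "acetate"): 2.0, ("B", "acetate"): 7.0}
        v1 = wf.aggregate_metabolite_flux(_fake_solution(base), profile, "acetate")
        scaled = {k: 3.0 * v for k, v in base.items()}
        v3 = wf.aggregate_metabolite_flux(_fake_solution(scaled), profile, "acetate")
        assert v3 == pytest.approx(3.0 * v1)


class TestPanelsAndClassification:
    def test_panel_totals_by_hand(self):
        fluxes = {"acetate": 6.0, "propionate": 2.0, "butyrate": 1.0,
                  "isovalerate": 0.3}
        assert wf.panel_totals(fluxes) == (pytest.approx(9.0), pytest.approx(0.3))

    def test_empty_mapping_and_non_panel_compounds(self):
        assert wf.panel_totals({}) == (0.0, 0.0)
        with_lactate = {"acetate": 6.0, "lactate": 99.0}
        assert wf.panel_totals(with_lactate)[0] == pytest.approx(6.0)

    def test_relative_variation_examples(self):
        assert wf.relative_variation(11.17, 10.0) == pytest.approx(11.7)
        assert wf.relative_variation(10.0, 10.0) == 0.0
        assert wf.relative_variation(0.0, 10.0) == pytest.approx(-100.0)
        assert wf.relative_variation(5.0, 0.0) is None

    @pytest.mark.parametrize(
        "rel,expected",
        [(6.4, "increase"), (0.5, "no-change"), (-40.2, "decrease"),
         (1.0, "no-change"), (-1.0, "no-change")],
    )
    def test_classification_band_semantics(self, rel, expected):
        assert wf.classify_combination(rel, 1.0) == expected


def _tiny_screen_inputs():
    """Two-taxon, two-food world small enough for per-test screening."""
    models = [
        make_linear_taxon("Acet", "sugar", 0.5, products={"acetate": 1.0},
                          cofactors={"V": 1e-3}),
        make_linear_taxon("Prot", "amino", 0.4, products={"isovalerate": 0.5},
                          cofactors={"W": 1e-3}),
    ]
    profile = wf.renormalize(wf.AbundanceProfile({"Acet": 0.7, "Prot": 0.3}))
    community = wf.assemble_community(models, profile)
    foods = {
        "breastmilk": wf.FoodItem(
            "breastmilk", 0.65,
            {"sugar": 0.6, "amino": 0.3, "V": 0.01, "W": 0.01}, "milk"),
        "fiberfood": wf.FoodItem(
            "fiberfood", 0.8, {"sugar": 2.0, "V": 0.01, "W": 0.01}, "vegetable"),
        "meat": wf.FoodItem(
            "meat", 1.6, {"amino": 2.0, "V": 0.01, "W": 0.01}, "animal_protein"),
    }
    return models, profile, community, foods


class TestRunScreen:
    def test_fiber_food_classified_increase_by_construction(self):
        _, profile, community, foods = _tiny_screen_inputs()
        results = wf.run_screen(foods, set(), community, profile)
        by_id = {r.combination_id: r for r in results}
        assert by_id["fiberfood"].classification["total_scfa"] == "increase"
        assert by_id["meat"].classification["total_bcfa"] == "increase"
        assert by_id["meat"].classification["total_scfa"] == "decrease"

    def test_control_identity(self):
        _, profile, community, foods = _tiny_screen_inputs()
        results = wf.run_screen(foods, set(), community, profile)
        control = next(r for r in results if r.combination_id == "breastmilk")
        defined = [v for v in control.rel_variation.values() if v is not None]
        assert defined  # the panels at least are defined
        for value in defined:
            assert value == pytest.approx(0.0, abs=1e-9)
        for value in control.growth_rel_variation.values():
            assert value == pytest.approx(0.0, abs=1e-9)

    def test_screen_of_zero_foods_yields_control_only(self):
        models, profile, community, foods = _tiny_screen_inputs()
        milk_only = {"breastmilk": foods["breastmilk"]}
        results = wf.run_screen(milk_only, set(), community, profile)
        assert [r.combination_id for r in results] == ["breastmilk"]

    def test_combination_count_n_singles_plus_pairs_plus_controls(self):
        _, profile, community, foods = _tiny_screen_inputs()
        pairs = wf.all_pairs(["fiberfood", "meat"])
        results = wf.run_screen(foods, set(), community, profile, pairs=pairs)
        assert len(results) == 2 + 1 + 1  # singles + pair + milk control
        assert len(wf.all_pairs([f"f{i}" for i in range(12)])) == 66

    def test_results_sorted_by_total_scfa_descending(self):
        _, profile, community, foods = _tiny_screen_inputs()
        results = wf.run_screen(foods, set(), community, profile)
        totals = [r.total_scfa for r in results]
        assert totals == sorted(totals, reverse=True)

    def test_solver_failure_is_recorded_not_raised(self):
        _, profile, community, foods = _tiny_screen_inputs()
        foods = dict(foods)
        foods["poison"] = wf.FoodItem("poison", -1.0, {}) if False else wf.FoodItem(
            "poison", 0.001, {}
        )
        # a zero-composition food still screens; break it via missing food in pairs
        results = wf.run_screen(
            foods, set(), community, profile, pairs=[("poison", "ghost")]
        )
        failed = next(r for r in results if r.combination_id == "ghost+poison")
        assert failed.solver_status.startswith("error")
        assert len([r for r in results if not r.solver_status.startswith("error")]) >= 3


class TestExportReport:
    def test_matrix_shape_and_na_rendering(self, tmp_path):
        results = [
            wf.ScreenResult(
                combination_id="combo1",
                per_metabolite_flux={"acetate": 1.0},
                total_scfa=1.0, total_bcfa=0.0,
                rel_variation={"acetate": 5.0, "butyrate": None},
                growth_rel_variation={"A": 1.0},
                classification={"total_scfa": "increase", "total_bcfa": "no-change"},
                alpha_used=1.0, solver_status="optimal",
            ),
            wf.ScreenResult(
                combination_id="combo2",
                per_metabolite_flux={"acetate": 0.5},
                total_scfa=0.5, total_bcfa=0.0,
                rel_variation={"acetate": -2.0, "butyrate": 3.0},
                growth_rel_variation={"A": -1.0},
                classification={"total_scfa": "decrease", "total_bcfa": "no-change"},
                alpha_used=1.0, solver_status="optimal",
            ),
        ]
        written = wf.export_report(results, str(tmp_path / "r"))
        lines = (tmp_path / "r_relvar.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["combination", "acetate", "butyrate", "growth:A"]
        assert len(lines) == 3
        assert lines[1].split("\t")[2] == "NA"  # undefined variation cell
        reloaded = load_report(written[1])
        assert reloaded == results

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            wf.export_report([], "nowhere")

    def test_screen_outputs_byte_identical_across_runs(self, tmp_path):
        _, profile, community, foods = _tiny_screen_inputs()
        for run in ("one", "two"):
            results = wf.run_screen(
                foods, set(), community, profile,
                pairs=wf.all_pairs(["fiberfood", "meat"]),
            )
            wf.export_report(results, str(tmp_path / run))
        assert filecmp.cmp(
            tmp_path / "one_relvar.tsv", tmp_path / "two_relvar.tsv", shallow=False
        )
        assert filecmp.cmp(
            tmp_path / "one_full.json", tmp_path / "two_full.json", shallow=False
        )


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            "no_change_band: 2.5\n"
            "aggregate_mode: net\n"
            "total_energy: 500.0\n"
            "solver:\n"
            "  alpha_grid: [1.0, 0.5]\n"
            "  negligible_growth: 1.0e-5\n"
        )
        cfg = load_screen_config(str(path))
        assert cfg.no_change_band == 2.5
        assert cfg.aggregate_mode == "net"
        assert cfg.total_energy == 500.0
        assert cfg.solver.alpha_grid == (1.0, 0.5)
        assert cfg.solver.negligible_growth == 1e-5

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("not_a_setting: 1\n")
        with pytest.raises(ValueError, match="not_a_setting"):
            load_screen_config(str(path))
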