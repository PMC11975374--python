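"""Pathway model: scenario resolution, moiety-map postconditions,
conservation, perturbation signs and the de novo purine lump."""

from __future__ import annotations

import numpy as np
import pytest

from samtrace.pathway import (
    NoiseSpec,
    build_network,
    build_scenario,
    emit_peak_table,
    integrate,
    purine_cost_summary,
    simulate_tracer,
)


class TestBuildScenario:
    def test_defaults_disable_remethylation(self):
        scen = build_scenario(genotype="control", infected=False,
                              tracer="Met-13C5")
        assert scen.capacities["remethylation"] == 0.0
        assert scen.capacities["met_cth_bypass"] == 0.0

    def test_ahcy_knockdown_scales_only_ahcy(self):
        ctrl = build_scenario(genotype="control", infected=False)
        kd = build_scenario(genotype="Ahcy-RNAi", infected=False,
                            knockdown_factor=0.1)
        assert kd.capacities["ahcy_forward"] == pytest.approx(
            0.1 * ctrl.capacities["ahcy_forward"])
        assert kd.capacities["ahcy_reverse"] == pytest.approx(
            0.1 * ctrl.capacities["ahcy_reverse"])
        unchanged = set(ctrl.capacities) - {"ahcy_forward", "ahcy_reverse"}
        for name in unchanged:
            assert kd.capacities[name] == ctrl.capacities[name]

    def test_unknown_names_rejected_by_name(self):
        with pytest.raises(ValueError, match="Xdh-RNAi"):
            build_scenario(genotype="Xdh-RNAi")
        with pytest.raises(ValueError, match="Gln-13C5"):
            build_scenario(tracer="Gln-13C5")

    @pytest.mark.parametrize("field,value", [
        ("knockdown_factor", 0.0), ("knockdown_factor", 1.5),
        ("nutrient_supply", 0.0), ("nutrient_supply", 1.2),
    ])
    def test_parameter_ranges(self, field, value):
        with pytest.raises(ValueError):
            build_scenario(**{field: value})

    def test_infection_scales_inducible_kinases_up(self):
        uninf = build_scenario(genotype="control", infected=False)
        inf = build_scenario(genotype="control", infected=True)
        for name in ("adenosine_kinase", "adenylate_kinase_fwd",
                     "methyltransferase"):
            assert inf.capacities[name] > uninf.capacities[name]


class TestPurineCost:
    def test_lump_constants(self):
        net = build_network(build_scenario())
        assert purine_cost_summary(net) == {"atp_per_imp": 6,
                                            "steps_to_imp": 11}

    def test_lump_absent_errors(self):
        net = build_network(build_scenario())
        net = type(net)(net.pools,
                        [r for r in net.reactions if r.step_count is None])
        with pytest.raises(ValueError, match="de novo"):
            purine_cost_summary(net)


class TestMoietyMaps:
    """Label classes must follow the biochemistry of each tracer."""

    def test_met_tracer_class_structure(self, sim):
        res = sim(genotype="control", infected=True, tracer="Met-13C5")
        sah = res.class_fractions("SAH")
        assert sah["m+4"] > 0.01
        assert set(k for k, v in sah.items() if v > 1e-9) <= {"m+0", "m+4"}
        mta = res.class_fractions("MTA")
        assert mta["m+1"] > 0.001
        assert set(k for k, v in mta.items() if v > 1e-9) <= {"m+0", "m+1"}
        cth = res.class_fractions("CTH")
        assert set(k for k, v in cth.items() if v > 1e-9) <= {"m+0", "m+4"}
        # nucleotides never see methionine carbon
        for pool in ("Ado", "AMP", "ADP", "ATP"):
            assert res.labeled_fraction(pool) < 1e-9

    def test_met_tracer_sam_m4_only_from_impurity(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5")
        sam = res.class_fractions("SAM")
        assert sam["m+5"] > 0.01
        assert 0 < sam["m+4"] < sam["m+5"]
        # m+4:m+5 mirrors the 3% stock impurity (no remethylation source)
        assert sam["m+4"] / (sam["m+4"] + sam["m+5"]) == pytest.approx(
            0.03, abs=0.002)

    def test_ado_tracer_m5_only_and_requires_kinases(self, sim):
        res = sim(genotype="control", infected=True, tracer="Ado-13C5")
        for pool in ("Ado", "AMP", "ADP", "ATP", "SAM"):
            labeled = {k for k, v in res.class_fractions(pool).items()
                       if v > 1e-9 and k != "m+0"}
            assert labeled <= {"m+5"}, pool
        assert res.class_fractions("SAM")["m+5"] > 0.001
        # without the recycling kinases no label reaches SAM
        blocked = sim(genotype="control", infected=True, tracer="Ado-13C5",
                      capacities={"adenosine_kinase": 0.0})
        assert blocked.class_fractions("SAM").get("m+5", 0.0) < 1e-12

    def test_zero_uptake_keeps_pools_unlabeled(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5",
                  capacities={"met_uptake": 0.0})
        for pool in ("Met", "SAM", "SAH", "CTH", "MTA"):
            assert res.labeled_fraction(pool) < 1e-12

    def test_remethylation_produces_met_m4(self, sim):
        res = sim(genotype="control", infected=True, tracer="Met-13C5",
                  capacities={"remethylation": 2.0}, duration_min=60.0)
        met = res.class_fractions("Met")
        r = met["m+4"] / (met["m+4"] + met["m+5"])
        assert r > 0.05  # well above the 3% stock-impurity floor


class TestInvariants:
    def test_simplex_at_all_output_times(self, sim):
        res = sim(genotype="control", infected=True, tracer="Met-13C5")
        for t_index in range(len(res.times)):
            for pool in res.network.pools:
                total = float(
                    res.states[t_index, res.network.pool_slice(pool.name)].sum())
                if total <= 0:
                    continue
                s = sum(res.class_fractions(pool.name, t_index).values())
                assert s == pytest.approx(1.0, abs=1e-9), pool.name

    def test_closed_model_conserves_labeled_moieties(self):
        scen = build_scenario(
            genotype="control", infected=False, tracer="none",
            capacities={"met_uptake": 0.0, "met_efflux": 0.0,
                        "ent_export": 0.0, "de_novo_purine": 0.0,
                        "mta_clearance": 0.0, "ado_uptake": 0.0})
        net = build_network(scen, labeled=True)
        y0 = net.initial_state(label_dists={
            "Met": np.array([0.4, 0.1, 0.0, 0.5]),   # m+0 / m+4 / m+1 / m+5
            "ATP": np.array([0.7, 0.3]),
        })
        me0 = net.labeled_moiety_amount(y0, "me")
        ad0 = net.labeled_moiety_amount(y0, "ad")
        _, states = integrate(net, y0, 20.0, 0.01, record_every=500)
        for y in states:
            assert net.labeled_moiety_amount(y, "me") == pytest.approx(
                me0, rel=1e-9)
            assert net.labeled_moiety_amount(y, "ad") == pytest.approx(
                ad0, rel=1e-9)

    def test_step_halving_convergence(self):
        kw = dict(genotype="control", infected=True, tracer="Met-13C5",
                  preequilibrate_min=60.0)
        a = simulate_tracer(build_scenario(dt_min=0.01, **kw))
        b = simulate_tracer(build_scenario(dt_min=0.005, **kw))
        for pool in ("Met", "SAM", "SAH", "MTA", "CTH"):
            fa, fb = a.class_fractions(pool), b.class_fractions(pool)
            for cls in fa:
                assert abs(fa[cls] - fb[cls]) < 1e-6

    def test_nutrient_supply_monotonicity(self, sim):
        """Starved cells push adenosine out instead of recycling it."""
        export_shares, recycle_shares = [], []
        for ns in (1.0, 0.6, 0.3):
            res = sim(genotype="control", infected=True, tracer="none",
                      nutrient_supply=ns)
            export = res.flux_total("ent_export")
            recycle = res.flux_total("adenosine_kinase")
            ada = res.flux_total("ada")
            total = export + recycle + ada
            export_shares.append(export / total)
            recycle_shares.append(recycle / total)
        assert export_shares[0] < export_shares[1] < export_shares[2]
        assert recycle_shares[0] > recycle_shares[1] > recycle_shares[2]


class TestPerturbationSigns:
    def test_ahcy_rnai_accumulates_sah_and_lowers_mi(self, sim):
        ctrl = sim(genotype="control", infected=True, tracer="Met-13C5")
        kd = sim(genotype="Ahcy-RNAi", infected=True, tracer="Met-13C5")
        assert kd.endpoint_amount("SAH") > 2 * ctrl.endpoint_amount("SAH")
        mi_ctrl = ctrl.endpoint_amount("SAM") / ctrl.endpoint_amount("SAH")
        mi_kd = kd.endpoint_amount("SAM") / kd.endpoint_amount("SAH")
        assert mi_kd < mi_ctrl

    def test_ahcy_rnai_flattens_export_rise(self, sim):
        rises = {}
        for genotype in ("control", "Ahcy-RNAi"):
            u = sim(genotype=genotype, infected=False, tracer="none")
            i = sim(genotype=genotype, infected=True, tracer="none")
            rises[genotype] = (i.exported_purines()["total"]
                               - u.exported_purines()["total"])
        assert rises["control"] > 0
        assert rises["Ahcy-RNAi"] < 0.5 * rises["control"]

    def test_adk3_rnai_blunts_infected_amp_rise(self, sim):
        ratios = {}
        for genotype in ("control", "Adk3-RNAi"):
            u = sim(genotype=genotype, infected=False, tracer="none")
            i = sim(genotype=genotype, infected=True, tracer="none")
            ratios[genotype] = (i.endpoint_amount("AMP")
                                / u.endpoint_amount("AMP"))
        assert ratios["control"] > 1.0
        assert ratios["Adk3-RNAi"] < ratios["control"]


class TestPeakEmission:
    def test_noise_off_is_bit_identical(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5")
        results = {"s1": ("g", res)}
        a = emit_peak_table(results, NoiseSpec(sd=0.0))
        b = emit_peak_table(results, NoiseSpec(sd=0.0))
        assert a.equals(b)

    def test_seeding_contract(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5")
        results = {"s1": ("g", res)}
        a = emit_peak_table(results, NoiseSpec(sd=0.2, seed=7))
        b = emit_peak_table(results, NoiseSpec(sd=0.2, seed=7))
        c = emit_peak_table(results, NoiseSpec(sd=0.2, seed=8))
        assert a.equals(b)
        assert not a["peak_area"].equals(c["peak_area"])

    def test_homocysteine_flagged_not_detected(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5")
        table = emit_peak_table({"s1": ("g", res)})
        hcy = table[table["metabolite"] == "homocysteine"]
        assert len(hcy) > 0
        assert not hcy["detected"].any()
        assert hcy["peak_area"].isna().all()

    def test_negative_response_factor_rejected(self, sim):
        res = sim(genotype="control", infected=False, tracer="Met-13C5")
        with pytest.raises(ValueError, match="response factor"):
            emit_peak_table({"s1": ("g", res)},
                            response_factors={"SAM": -1.0})
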