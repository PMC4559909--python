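import numpy as np
import pytest
from scipy.optimize import brentq

from vegfsema import binding
from vegfsema.binding import (
    CELLS, SEMA3S, CompiledNetwork, default_network, default_parameters,
    enumerate_network, expression_scale_factors, p_value_stars,
    scale_production, simulate_to_steady_state, steady_state_root,
)


class TestNetworkStructure:
    def test_no_direct_sema_vegfr_binding(self):
        net, _ = default_network()
        for rx in net.reactions:
            if rx["kind"] == "binding" and rx["ligand"].startswith("SEMA3"):
                assert rx["receptor"] in ("N1", "N2")

    def test_both_coupling_routes_to_vegf_ternary(self):
        net, _ = default_network()
        keys = {rx["key"] for rx in net.reactions
                if rx["kind"] == "coupling" and rx["cell"] == "EC"}
        assert "V165_R2+N1" in keys
        assert "V165_N1+R2" in keys

    def test_species_and_reaction_counts_match_rule_closure(self):
        """Independent enumeration: count what the rules must generate."""
        net, _ = default_network()
        n_ligands = 13
        n_binary_per_cell = sum(len(v) for v in binding.BINDING_RULES.values())  # 30
        n_ternary_per_cell = 1 + 2 * len(SEMA3S)  # VEGF ternary + Sema x {N1,N2}
        n_receptors = 6
        expected_species = n_ligands + 2 * (n_receptors + n_binary_per_cell
                                            + n_ternary_per_cell)
        assert len(net.species) == expected_species
        n_couplings_per_cell = 2 + 2 * len(SEMA3S)
        assert len(net.reactions) == 2 * (n_binary_per_cell + n_couplings_per_cell)

    def test_complexes_decompose_into_monomers(self):
        net, _ = default_network()
        for rx in net.reactions:
            lhs = {}
            for s in rx["reactants"]:
                for mono, c in net.composition[s].items():
                    lhs[mono] = lhs.get(mono, 0) + c
            assert lhs == net.composition[rx["product"]]

    def test_detailed_balance_enforced_at_construction(self):
        params = default_parameters()
        CompiledNetwork(params)  # consistent defaults pass
        bad = params.copy()
        bad.kc_off["V165_N1+R2"] *= 1.5
        with pytest.raises(ValueError, match="detailed-balance"):
            CompiledNetwork(bad)


class TestSteadyState:
    def test_zero_secretion_closed_form_receptors(self):
        params = default_parameters()
        for key in params.secretion:
            params.secretion[key] = 0.0
        res = simulate_to_steady_state(CompiledNetwork(params))
        from scipy.constants import N_A
        for cell in CELLS:
            conv = params.cell_density[cell] / N_A * 1e12
            for rec in binding.RECEPTORS:
                expected = params.insertion[(cell, rec)] * conv / params.k_int[cell]
                assert res.species[f"{cell}:{rec}"] == pytest.approx(expected, rel=1e-5)
        # no ligand -> no complexes
        complexes = [s for s in res.species.index if "_" in s]
        assert res.species[complexes].max() < 1e-12

    def test_single_ligand_single_receptor_matches_closed_form(self):
        """Reduced network vs an independently solved 3-species balance."""
        params = default_parameters()
        for key in params.secretion:
            params.secretion[key] = 0.0
        for key in params.insertion:
            params.insertion[key] = 0.0
        # keep only VEGF121 (via VEGFA with isoform fraction 0) and EC VEGFR2
        params.vegfa_iso_fraction_165 = 0.0
        params.secretion[("TUM", "VEGFA")] = 0.02
        params.insertion[("EC", "R2")] = 2.8
        res = simulate_to_steady_state(CompiledNetwork(params))

        from scipy.constants import N_A
        phi = params.fluid_fraction
        S_L = 0.02 * params.cell_density["TUM"] / N_A * 1e12
        s_R = 2.8 * params.cell_density["EC"] / N_A * 1e12
        kon = params.kon[("V121", "R2")] * 1e-12 / phi
        koff = params.koff[("V121", "R2")]
        kint = params.k_int["EC"]
        kdeg = params.k_deg

        def residual(L):
            # at fixed L: R and C from their linear balances
            R = s_R / (kint + kon * L * kint / (koff + kint))
            C = kon * L * R / (koff + kint)
            return S_L - kon * L * R + koff * C - kdeg * L

        L = brentq(residual, 1e-12, 1e6, xtol=1e-15)
        R = s_R / (kint + kon * L * kint / (koff + kint))
        C = kon * L * R / (koff + kint)
        assert res.species["V121"] == pytest.approx(L, rel=1e-5)
        assert res.species["EC:R2"] == pytest.approx(R, rel=1e-5)
        assert res.species["EC:V121_R2"] == pytest.approx(C, rel=1e-5)

    def test_ode_agrees_with_algebraic_root_solve(self, nominal_steady_state):
        res, compiled = nominal_steady_state
        x_ode = res.species.to_numpy()
        x_alg = steady_state_root(compiled, x_ode)
        big = x_ode > 1e-6 * x_ode.max()
        rel = np.abs(x_alg - x_ode)[big] / x_ode[big]
        assert rel.max() < 1e-3

    def test_nonnegative_at_steady_state(self, nominal_steady_state):
        res, _ = nominal_steady_state
        assert (res.species.to_numpy() >= 0).all()

    def test_closed_system_mass_conservation(self):
        params = default_parameters()
        compiled = CompiledNetwork(params, closed_system=True)
        rng = np.random.default_rng(0)
        x0 = rng.uniform(1.0, 100.0, size=compiled.n_species)
        from scipy.integrate import solve_ivp
        sol = solve_ivp(compiled.rhs, (0.0, 5e4), x0, method="BDF",
                        jac=compiled.jac, rtol=1e-10, atol=1e-10)
        assert sol.success
        before = compiled.monomer_totals(x0)
        after = compiled.monomer_totals(sol.y[:, -1])
        assert np.abs(after - before).max() / np.abs(before).max() < 1e-8

    def test_monotone_in_own_ligand_secretion(self, default_params):
        base = simulate_to_steady_state(CompiledNetwork(default_params))
        for gene, aggregate in (("VEGFA", "vegfa_vegfr2"), ("VEGFA", "vegfa_vegfr1"),
                                ("SEMA3C", "sema3_nrp_plxna")):
            prev = base.aggregates[("EC", aggregate)]
            for factor in (2.0, 4.0):
                p = default_params.copy()
                for cell in CELLS:
                    p.secretion[(cell, gene)] *= factor
                cur = simulate_to_steady_state(CompiledNetwork(p)).aggregates[
                    ("EC", aggregate)]
                assert cur > prev
                prev = cur

    def test_weak_competition_at_defaults(self, default_params, nominal_steady_state):
        """Doubling every Sema3 secretion barely moves VEGFA-VEGFR2 binding."""
        res, _ = nominal_steady_state
        p = default_params.copy()
        for cell in CELLS:
            for s in SEMA3S:
                p.secretion[(cell, s)] *= 2.0
        res2 = simulate_to_steady_state(CompiledNetwork(p))
        a1 = res.aggregates[("EC", "vegfa_vegfr2")]
        a2 = res2.aggregates[("EC", "vegfa_vegfr2")]
        assert abs(a2 - a1) / a1 < 0.01
        # while the semaphorin ternary itself responds strongly
        t1 = res.aggregates[("EC", "sema3_nrp_plxna")]
        t2 = res2.aggregates[("EC", "sema3_nrp_plxna")]
        assert t2 / t1 > 1.5


class TestProductionScaling:
    def test_normal_mean_sample_has_unit_factors(self, sim_cohort):
        m, _ = sim_cohort
        # overwrite a primary sample with the normal-group linear mean
        m2 = m.select_samples(list(m.sample_ids))
        normal_mean_linear = (2.0 ** m2.group_values("normal")).mean(axis=0)
        m2.values.iloc[20] = np.log2(normal_mean_linear)
        factors = expression_scale_factors(m2, m2.sample_ids[20])
        for gene, f in factors.items():
            assert f == pytest.approx(1.0, rel=1e-10), gene

    def test_one_log2_unit_doubles_rate(self, sim_cohort):
        m, _ = sim_cohort
        m2 = m.select_samples(list(m.sample_ids))
        normal_mean_linear = (2.0 ** m2.group_values("normal")).mean(axis=0)
        m2.values.iloc[20] = np.log2(normal_mean_linear) + 1.0
        factors = expression_scale_factors(m2, m2.sample_ids[20])
        assert factors["VEGFA"] == pytest.approx(2.0, rel=1e-10)

    def test_plxna_family_factor_is_linear_sum_ratio(self, sim_cohort):
        m, _ = sim_cohort
        sid = m.sample_ids[20]
        factors = expression_scale_factors(m, sid)
        plxna = ("PLXNA1", "PLXNA2", "PLXNA3", "PLXNA4")
        lin = sum(2.0 ** m.values.at[sid, g] for g in plxna)
        ref = np.mean(np.sum(2.0 ** m.group_values("normal")[list(plxna)], axis=1))
        assert factors["PLXNA"] == pytest.approx(lin / ref, rel=1e-10)

    def test_only_tumor_rates_scaled(self, sim_cohort, default_params):
        m, _ = sim_cohort
        scaled = scale_production(default_params, m, m.sample_ids[15])
        for (cell, key), v in scaled.secretion.items():
            if cell == "EC":
                assert v == default_params.secretion[(cell, key)]
        for (cell, key), v in scaled.insertion.items():
            if cell == "EC":
                assert v == default_params.insertion[(cell, key)]

    def test_absent_gene_is_error(self, default_params):
        import pandas as pd
        from vegfsema.panel import ExpressionMatrix
        values = pd.DataFrame(np.zeros((2, 1)), columns=["VEGFA"], index=["a", "b"])
        md = pd.DataFrame({"tissue_type": ["normal", "primary"]}, index=values.index)
        with pytest.raises(ValueError, match="absent"):
            scale_production(default_params, ExpressionMatrix(values, md), "b")


class TestPopulationOutputs:
    def test_identical_samples_identical_outputs(self, sim_cohort, default_params):
        m, _ = sim_cohort
        full = m.select_samples(list(m.sample_ids))
        # two primary samples forced identical (normal reference untouched)
        full.values.iloc[13] = full.values.iloc[12]
        results = binding.run_population(default_params, full,
                                         sample_ids=list(full.sample_ids[12:14]))
        a = results[0].species.to_numpy()
        b = results[1].species.to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_doubling_vegfa_increases_vegfr2_binding(self, sim_cohort, default_params):
        m, _ = sim_cohort
        m2 = m.select_samples(list(m.sample_ids))
        sid = m2.sample_ids[20]
        res1 = binding.run_population(default_params, m2, sample_ids=[sid])[0]
        m2.values.at[sid, "VEGFA"] += 1.0
        res2 = binding.run_population(default_params, m2, sample_ids=[sid])[0]
        assert (res2.aggregates[("EC", "vegfa_vegfr2")]
                > res1.aggregates[("EC", "vegfa_vegfr2")])

    def test_population_medians_ordered_as_in_tissue_groups(self, binding_population):
        """Accelerator lowest in primary; brake falls normal->primary->met."""
        results, m = binding_population
        df = binding.aggregates_frame(results, m)
        med = df.groupby("tissue_type").median(numeric_only=True)
        v = med["EC:vegfa_vegfr2"]
        assert v["primary"] < v["normal"] and v["primary"] < v["metastatic"]
        t = med["EC:sema3_nrp_plxna"]
        assert t["normal"] > t["primary"] > t["metastatic"]

    def test_all_samples_converge(self, binding_population):
        results, _ = binding_population
        assert all(r.converged for r in results)


class TestDerivedTables:
    @pytest.mark.parametrize("p,stars", [
        (0.03, "*"), (0.005, "**"), (0.0005, "***"), (0.2, ""),
    ])
    def test_star_annotation(self, p, stars):
        assert p_value_stars(p) == stars

    def test_group_tests_annotations_consistent(self, binding_population):
        results, m = binding_population
        tab = binding.group_compare_complexes(results, m)
        for _, row in tab.iterrows():
            assert row["stars"] == p_value_stars(row["p"])

    def test_cross_pair_r2_much_smaller_than_direct(self, binding_population):
        results, m = binding_population
        fits = binding.variance_explained(results, m).set_index(
            ["predictor", "response"])
        direct_v = fits.at[("VEGFA", "vegfa_vegfr2"), "r2"]
        cross_v = fits.at[("SEMA3_total", "vegfa_vegfr2"), "r2"]
        direct_s = fits.at[("SEMA3_total", "sema3_nrp_plxna"), "r2"]
        cross_s = fits.at[("VEGFA", "sema3_nrp_plxna"), "r2"]
        assert cross_v < 0.5 * direct_v
        assert cross_s < 0.5 * direct_s
        assert direct_v > 0.5 and direct_s > 0.5

    def test_exact_log_linear_relation_gives_r2_one(self, sim_cohort):
        import pandas as pd
        m, _ = sim_cohort
        fake = []
        for sid in m.sample_ids:
            agg = {("EC", "vegfa_vegfr2"): 10 ** (0.3 * m.values.at[sid, "VEGFA"]),
                   ("EC", "vegfa_vegfr1"): 10 ** (0.2 * m.values.at[sid, "VEGFA"]),
                   ("EC", "sema3_nrp_plxna"): 1.0,
                   ("TUM", "vegfa_vegfr2"): 1.0, ("TUM", "vegfa_vegfr1"): 1.0,
                   ("TUM", "sema3_nrp_plxna"): 1.0}
            fake.append(binding.SampleSimulationResult(
                sample_id=sid, species=pd.Series(dtype=float), aggregates=agg,
                converged=True, t_final=0.0, max_rel_rate_per_hour=0.0))
        fits = binding.variance_explained(fake, m).set_index(
            ["predictor", "response"])
        assert fits.at[("VEGFA", "vegfa_vegfr2"), "r2"] == pytest.approx(1.0)

    def test_quadrant_benign_split(self, binding_population):
        results, m = binding_population
        quad = binding.quadrant_classify(results, m)
        benign = quad[quad["tissue_type"] == "normal"]
        # medians split the benign group about evenly on each axis
        assert 0.25 <= benign["accelerator_on"].mean() <= 0.75
        assert 0.25 <= benign["brake_off"].mean() <= 0.75

    def test_quadrant_tie_rule(self, sim_cohort):
        """A sample exactly at both benign medians is accel OFF / brake ON."""
        import pandas as pd
        m, _ = sim_cohort
        fake = []
        normal = set(m.metadata.index[m.tissue_mask("normal")])
        for i, sid in enumerate(m.sample_ids):
            acc, brake = (3.0, 5.0) if sid in normal else (3.0 + i, 5.0 + i)
            agg = {("EC", "vegfa_vegfr2"): acc,
                   ("EC", "vegfa_vegfr1"): 1.0,
                   ("EC", "sema3_nrp_plxna"): brake,
                   ("TUM", "vegfa_vegfr2"): 1.0, ("TUM", "vegfa_vegfr1"): 1.0,
                   ("TUM", "sema3_nrp_plxna"): 1.0}
            fake.append(binding.SampleSimulationResult(
                sample_id=sid, species=pd.Series(dtype=float), aggregates=agg,
                converged=True, t_final=0.0, max_rel_rate_per_hour=0.0))
        quad = binding.quadrant_classify(fake, m)
        assert quad.attrs["thresholds"] == {"accelerator": 3.0, "brake": 5.0}
        at_tie = quad.loc[sorted(normal)]
        assert (~at_tie["accelerator_on"]).all()
        assert (~at_tie["brake_off"]).all()

    def test_metastases_enriched_in_accel_on_brake_off(self, binding_population):
        results, m = binding_population
        quad = binding.quadrant_classify(results, m)
        met = quad[quad["tissue_type"] == "metastatic"]
        prim = quad[quad["tissue_type"] == "primary"]
        met_onoff = (met["accelerator_on"] & met["brake_off"]).mean()
        prim_onoff = (prim["accelerator_on"] & prim["brake_off"]).mean()
        assert met_onoff > 0.5
        assert met_onoff > prim_onoff
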