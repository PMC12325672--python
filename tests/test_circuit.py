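import numpy as np
import pandas as pd
import pytest

from m1beta import cells, circuit, engine


class TestDelayLaw:
    @pytest.mark.parametrize(
        "d, expected", [(0.0, 2.0), (500.0, 3.0), (100.0, 2.2)]
    )
    def test_examples(self, d, expected):
        assert circuit.compute_delay(d) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            circuit.compute_delay(-1.0)

    def test_exact_on_every_edge(self, small_network):
        net = small_network
        pos = net.neurons.set_index("id")[["x", "y", "z"]]
        pre = pos.loc[net.edges["pre"]].to_numpy()
        post = pos.loc[net.edges["post"]].to_numpy()
        d = np.linalg.norm(pre - post, axis=1)
        np.testing.assert_allclose(
            net.edges["delay_ms"].to_numpy() - 2.0, d / 500.0, rtol=0, atol=1e-9
        )


class TestNMDAFactor:
    def test_values(self):
        assert circuit.nmda_voltage_factor(0.0) == pytest.approx(1 / 1.28)
        expected = 1.0 / (1.0 + 0.28 * np.exp(0.062 * 70.0))
        assert circuit.nmda_voltage_factor(-70.0) == pytest.approx(expected)

    def test_monotone_and_saturating(self):
        v = np.linspace(-100, 100, 401)
        f = circuit.nmda_voltage_factor(v)
        assert np.all(np.diff(f) > 0)
        assert circuit.nmda_voltage_factor(400.0) == pytest.approx(1.0, abs=1e-6)


class TestConnectionKernel:
    def test_probability_examples(self):
        rule = circuit.ConnectionRule("a", "b", p_con=0.2, v_con_mv=0.5, kind="E")
        assert circuit.connection_probability(rule, 0.0) == pytest.approx(0.2)
        assert circuit.connection_probability(rule, 100.0) == pytest.approx(
            0.2 * np.exp(-1)
        )
        assert circuit.connection_probability(rule, 200.0) == pytest.approx(
            0.2 * np.exp(-2)
        )

    def test_kernel_slope_recovered(self, kernel_test_network, all_models):
        """log empirical connection probability vs distance has slope
        -1/lambda within 10% (center cells, pre-correction regime)."""
        geo, neurons, rule = kernel_test_network
        edges = circuit.build_edges(
            neurons, [rule], all_models, seed=3, border_correction=True
        )
        r = np.hypot(neurons["x"], neurons["y"])
        center_ids = set(neurons.loc[r < 60, "id"])
        pos = neurons.set_index("id")[["x", "y", "z"]]
        # pair distances for center post cells
        post_sel = neurons[neurons["id"].isin(center_ids)]
        d_mat = np.linalg.norm(
            post_sel[["x", "y", "z"]].to_numpy()[:, None, :]
            - neurons[["x", "y", "z"]].to_numpy()[None, :, :],
            axis=2,
        )
        self_pair = (
            post_sel["id"].to_numpy()[:, None] == neurons["id"].to_numpy()[None, :]
        )
        d_all = d_mat[~self_pair].ravel()
        conn = edges[edges["post"].isin(center_ids)]
        d_conn = np.linalg.norm(
            pos.loc[conn["pre"]].to_numpy() - pos.loc[conn["post"]].to_numpy(),
            axis=1,
        )
        bins = np.arange(0, 250, 25)
        possible, _ = np.histogram(d_all, bins)
        realized, _ = np.histogram(d_conn, bins)
        ok = possible > 200
        p_emp = realized[ok] / possible[ok]
        centers = 0.5 * (bins[:-1] + bins[1:])[ok]
        keep = p_emp > 0
        slope = np.polyfit(centers[keep], np.log(p_emp[keep]), 1)[0]
        assert slope == pytest.approx(-1.0 / 100.0, rel=0.10)

    def test_border_correction_flattens_in_degree(
        self, kernel_test_network, all_models
    ):
        geo, neurons, rule = kernel_test_network
        r = np.hypot(neurons["x"], neurons["y"])
        inner = neurons.loc[r < np.quantile(r, 0.25), "id"]
        outer = neurons.loc[r > np.quantile(r, 0.75), "id"]

        def mean_indeg(border_correction):
            edges = circuit.build_edges(
                neurons,
                [rule],
                all_models,
                seed=4,
                border_correction=border_correction,
            )
            indeg = edges.groupby("post").size()
            return (
                indeg.reindex(inner).fillna(0).mean(),
                indeg.reindex(outer).fillna(0).mean(),
            )

        i_c, o_c = mean_indeg(True)
        assert abs(o_c - i_c) / i_c < 0.05
        i_u, o_u = mean_indeg(False)
        assert (i_u - o_u) / i_u > 0.20


class TestPlacement:
    def test_full_scale_count_near_10073(self):
        pops = circuit.default_populations()
        total = sum(p.full_count for p in pops)
        assert abs(total - 10073) / 10073 < 0.01

    def test_scaling_and_layer_confinement(self):
        geo = circuit.Geometry()
        pops = circuit.default_populations()
        n = circuit.place_neurons(geo, pops, scale=0.1, seed=0)
        full = {p.name: p.full_count for p in pops}
        for pop, grp in n.groupby("pop"):
            assert len(grp) == round(0.1 * full[pop])
        z0, z1 = geo.layer_depth_um("L5B")
        pt = n[n["pop"] == "PT5B"]
        assert pt["z"].between(z0, z1).all()
        r = np.hypot(n["x"], n["y"])
        assert (r <= geo.radius_um).all()

    def test_same_seed_reproduces_coordinates(self):
        geo = circuit.Geometry()
        pops = circuit.default_populations()
        a = circuit.place_neurons(geo, pops, 0.05, seed=7)
        b = circuit.place_neurons(geo, pops, 0.05, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_count_population_kept_with_warning(self):
        geo = circuit.Geometry()
        pops = [circuit.PopulationSpec("PT5B", "PT5B", "L5B", 4)]
        with pytest.warns(UserWarning):
            n = circuit.place_neurons(geo, pops, scale=0.05, seed=0)
        assert len(n) == 1


class TestEdges:
    def test_unknown_population_rejected(self, all_models):
        geo = circuit.Geometry()
        pops = [circuit.PopulationSpec("PT5B", "PT5B", "L5B", 50)]
        neurons = circuit.place_neurons(geo, pops, 1.0, seed=0)
        bad = circuit.ConnectionRule("ghost", "PT5B", 0.1, 0.5, "E")
        with pytest.raises(cells.ConfigurationError):
            circuit.build_edges(neurons, [bad], all_models, seed=0)

    def test_no_self_edges_and_synapse_conservation(self, small_network):
        e = small_network.edges
        assert (e["pre"] != e["post"]).all()
        assert (e["nsyn"] * 1).sum() == e["nsyn"].sum()  # conservation

    def test_pv_edges_land_perisomatically(self, small_network, all_models):
        e = small_network.edges
        cls = small_network.neurons.set_index("id")["cell_class"]
        pv_onto_e = e[
            (e["receptor"] == "PV")
            & (cls.loc[e["post"]].isin(["PT5B", "IT", "CT"]).to_numpy())
        ]
        assert len(pv_onto_e)
        for post_cls, grp in pv_onto_e.groupby(cls.loc[pv_onto_e["post"]].to_numpy()):
            model = all_models[post_cls]
            path = model.path_distance_to_soma()
            assert np.all(path[grp["comp"].to_numpy()] <= 50.0)

    def test_som_edges_target_apical(self, small_network, all_models):
        e = small_network.edges
        cls = small_network.neurons.set_index("id")["cell_class"]
        som_e = e[
            (e["receptor"] == "SOM_E")
            & (cls.loc[e["post"]].isin(["PT5B", "IT", "CT"]).to_numpy())
        ]
        assert len(som_e)
        for post_cls, grp in som_e.groupby(cls.loc[som_e["post"]].to_numpy()):
            model = all_models[post_cls]
            zones = np.array([c.zone for c in model.compartments])
            assert set(zones[grp["comp"].to_numpy()]) <= {"apical"}

    def test_roundtrip_save_load(self, small_network, tmp_path):
        small_network.save(tmp_path / "net")
        loaded = circuit.NetworkInstance.load(tmp_path / "net")
        pd.testing.assert_frame_equal(
            loaded.neurons, small_network.neurons, check_dtype=False
        )
        assert len(loaded.edges) == len(small_network.edges)


class TestEPSPNormalization:
    def test_unitary_epsp_within_10pct(self, it_cell):
        w = engine.calibrate_unitary_weight(it_cell, 2, "E", 0.5)
        amp = engine.measure_psp(it_cell, 2, "E", w)
        assert amp == pytest.approx(0.5, rel=0.10)
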