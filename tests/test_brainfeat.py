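import math

import numpy as np
import pandas as pd
import pytest

from lingbrain.brainfeat import (NetworkAtlas, TimeSeriesPanel,
                                 assemble_connectivity_matrix,
                                 connectivity_measure_names, connectivity_vector,
                                 default_morphometry_schema, fisher_z,
                                 network_cohesiveness, network_integration,
                                 read_morphometry_table)
from lingbrain.errors import (AtlasError, DomainError, NonPositiveValue,
                              SchemaViolation, ZeroVarianceNode)
from lingbrain.synthgen import default_atlas, generate_morphometry


def panel_from(arrays: dict) -> TimeSeriesPanel:
    return TimeSeriesPanel(subject_id="s", series={k: np.asarray(v, float)
                                                   for k, v in arrays.items()})


def orthonormal_zero_mean(T: int = 16):
    """Orthonormal zero-mean basis rows for building exact-correlation series."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(T, T))
    A -= A.mean(axis=0)
    q, _ = np.linalg.qr(A)
    return q.T


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061, abs=1e-7)

    def test_clipped_at_unity(self):
        z = fisher_z(1.0)
        assert math.isfinite(z)
        assert z == pytest.approx(math.atanh(1 - 1e-7))

    def test_odd_symmetry(self):
        for r in (0.1, 0.45, 0.99):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    def test_out_of_domain(self):
        with pytest.raises(DomainError):
            fisher_z(1.001)


class TestCohesiveness:
    def test_two_identical_nodes_hit_the_clip(self):
        x = np.sin(np.linspace(0, 8, 40))
        z = network_cohesiveness(panel_from({"a": x, "b": x}), {"a", "b"})
        assert z == pytest.approx(math.atanh(1 - 1e-7))

    def test_hand_built_three_node_panel(self):
        q = orthonormal_zero_mean()
        # pairwise correlations {ab: 0.5, ac: 0.5, bc: 0}
        a = q[0]
        b = 0.5 * q[0] + math.sqrt(0.75) * q[1]
        c = 0.5 * q[0] - (0.25 / math.sqrt(0.75)) * q[1] + math.sqrt(
            1 - 0.25 - 0.25 / 0.75 * 0.25 / 1) * q[2]
        # recompute the exact third coefficient so ||c|| = 1
        c = 0.5 * q[0] - (0.25 / math.sqrt(0.75)) * q[1]
        c = c + math.sqrt(1 - (c @ c)) * q[2]
        p = panel_from({"a": a, "b": b, "c": c})
        expected = (fisher_z(0.5) + fisher_z(0.5) + fisher_z(0.0)) / 3
        assert network_cohesiveness(p, {"a", "b", "c"}) == pytest.approx(
            expected, abs=1e-10)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(100):
            data = rng.normal(size=(5, 30))
            p = panel_from({f"n{i}": data[i] for i in range(5)})
            nodes = [f"n{i}" for i in range(5)]
            zs = []
            for i in range(5):
                for j in range(i + 1, 5):
                    r = np.corrcoef(data[i], data[j])[0, 1]
                    zs.append(fisher_z(r))
            assert network_cohesiveness(p, nodes) == pytest.approx(
                np.mean(zs), abs=1e-10)

    def test_invariant_to_node_order_and_affine_transform(self, rng):
        data = rng.normal(size=(4, 50))
        nodes = ["a", "b", "c", "d"]
        p1 = panel_from(dict(zip(nodes, data)))
        z1 = network_cohesiveness(p1, nodes)
        assert network_cohesiveness(p1, nodes[::-1]) == pytest.approx(z1)
        p2 = panel_from(dict(zip(nodes, 3.5 * data + 11.0)))
        assert network_cohesiveness(p2, nodes) == pytest.approx(z1, abs=1e-10)

    def test_negating_all_series_changes_nothing(self, rng):
        data = rng.normal(size=(4, 50))
        nodes = ["a", "b", "c", "d"]
        z1 = network_cohesiveness(panel_from(dict(zip(nodes, data))), nodes)
        z2 = network_cohesiveness(panel_from(dict(zip(nodes, -data))), nodes)
        assert z2 == pytest.approx(z1, abs=1e-12)

    def test_monotone_in_shared_signal_amplitude(self):
        rng = np.random.default_rng(7)
        T, n_nodes = 1000, 6
        shared = rng.normal(size=T)
        noise = rng.normal(size=(n_nodes, T))
        values = []
        for amp in (0.0, 0.5, 1.0, 2.0, 4.0):
            p = panel_from({f"n{i}": amp * shared + noise[i] for i in range(n_nodes)})
            values.append(network_cohesiveness(p, [f"n{i}" for i in range(n_nodes)]))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_zero_variance_node_named(self):
        p = panel_from({"flat": np.ones(20), "ok": np.arange(20.0)})
        with pytest.raises(ZeroVarianceNode, match="flat"):
            network_cohesiveness(p, {"flat", "ok"})


class TestIntegration:
    def test_copied_networks_hit_the_clip(self, rng):
        data = rng.normal(size=(2, 40))
        p = panel_from({"a1": data[0], "a2": data[1],
                        "b1": data[0], "b2": data[1]})
        z = network_integration(p, {"a1", "a2"}, {"b1", "b2"})
        assert z == pytest.approx(math.atanh(1 - 1e-7))

    def test_independent_networks_near_zero(self):
        rng = np.random.default_rng(8)
        T = 2000
        p = panel_from({f"{g}{i}": rng.normal(size=T)
                        for g in "ab" for i in range(3)})
        z = network_integration(p, {"a0", "a1", "a2"}, {"b0", "b1", "b2"})
        assert abs(z) < 0.1

    def test_sign_flips_when_one_side_negated(self, rng):
        data = rng.normal(size=(4, 60))
        p1 = panel_from({"a0": data[0], "a1": data[1],
                         "b0": data[2], "b1": data[3]})
        p2 = panel_from({"a0": data[0], "a1": data[1],
                         "b0": -data[2], "b1": -data[3]})
        z1 = network_integration(p1, {"a0", "a1"}, {"b0", "b1"})
        z2 = network_integration(p2, {"a0", "a1"}, {"b0", "b1"})
        assert z2 == pytest.approx(-z1, abs=1e-12)

    def test_negating_everything_changes_nothing(self, rng):
        data = rng.normal(size=(4, 60))
        p1 = panel_from({"a0": data[0], "a1": data[1],
                         "b0": data[2], "b1": data[3]})
        p2 = panel_from({"a0": -data[0], "a1": -data[1],
                         "b0": -data[2], "b1": -data[3]})
        args = ({"a0", "a1"}, {"b0", "b1"})
        assert network_integration(p2, *args) == pytest.approx(
            network_integration(p1, *args), abs=1e-12)

    def test_overlapping_networks_rejected(self, rng):
        data = rng.normal(size=(3, 20))
        p = panel_from({"a": data[0], "b": data[1], "c": data[2]})
        with pytest.raises(AtlasError):
            network_integration(p, {"a", "b"}, {"b", "c"})


class TestConnectivityVector:
    def test_six_network_atlas_yields_eleven_measures(self, rng):
        atlas = default_atlas(nodes_per_network=3)
        p = TimeSeriesPanel("s", {n: rng.normal(size=30) for n in atlas.all_nodes})
        vec = connectivity_vector(p, atlas)
        assert len(vec) == 11
        assert sum(k.startswith("coh_") for k in vec) == 6
        assert sum(k.startswith("int_LAN_") for k in vec) == 5

    def test_two_network_atlas_yields_three(self, rng):
        atlas = NetworkAtlas({"LAN": {"l0", "l1"}, "AN": {"a0", "a1"}}, "LAN")
        p = TimeSeriesPanel("s", {n: rng.normal(size=30) for n in atlas.all_nodes})
        assert len(connectivity_vector(p, atlas)) == 3

    def test_all_pairs_option(self, rng):
        atlas = default_atlas(nodes_per_network=3)
        p = TimeSeriesPanel("s", {n: rng.normal(size=30) for n in atlas.all_nodes})
        assert len(connectivity_vector(p, atlas, all_pairs=True)) == 6 + 15

    def test_names_stable_and_columns_align(self, rng):
        atlas = default_atlas(nodes_per_network=3)
        vectors = {}
        for s in ("s1", "s2", "s3"):
            p = TimeSeriesPanel(s, {n: rng.normal(size=30) for n in atlas.all_nodes})
            vectors[s] = connectivity_vector(p, atlas)
        m = assemble_connectivity_matrix(vectors, atlas)
        assert m.shape == (3, 11)
        assert m.feature_names == connectivity_measure_names(atlas)

    def test_atlas_validation(self):
        with pytest.raises(AtlasError):
            NetworkAtlas({"LAN": {"a"}}, "LAN")                 # 1 network, 1 node
        with pytest.raises(AtlasError):
            NetworkAtlas({"LAN": {"a", "b"}, "DMN": {"b", "c"}}, "LAN")  # overlap
        with pytest.raises(AtlasError):
            NetworkAtlas({"A": {"a", "b"}, "B": {"c", "d"}}, "LAN")      # hub absent


class TestMorphometry:
    def test_default_schema_roundtrip(self, tmp_path):
        m = generate_morphometry(10, seed=0)
        path = tmp_path / "morph.tsv"
        m.to_tsv(path)
        loaded = read_morphometry_table(path)
        assert loaded.shape == (10, 88)
        assert loaded.meta["n_cortical_thickness"] == 68
        assert loaded.meta["n_subcortical_volume"] == 20

    def test_missing_hemisphere_lists_absent_names(self, tmp_path):
        m = generate_morphometry(5, seed=1)
        df = m.data[[c for c in m.data.columns if not c.startswith("rh_")]]
        df.to_csv(tmp_path / "half.tsv", sep="\t", index_label="subject_id")
        with pytest.raises(SchemaViolation) as err:
            read_morphometry_table(tmp_path / "half.tsv")
        assert str(err.value).count("rh_") == 34

    def test_negative_volume_names_subject_and_feature(self, tmp_path):
        m = generate_morphometry(5, seed=2)
        df = m.data.copy()
        df.iloc[2, 70] = -5.0
        df.to_csv(tmp_path / "neg.tsv", sep="\t", index_label="subject_id")
        with pytest.raises(NonPositiveValue) as err:
            read_morphometry_table(tmp_path / "neg.tsv")
        assert df.index[2] in str(err.value)
        assert df.columns[70] in str(err.value)

    def test_missing_values_need_explicit_imputation(self, tmp_path):
        m = generate_morphometry(5, seed=3)
        df = m.data.copy()
        df.iloc[1, 4] = np.nan
        df.to_csv(tmp_path / "nan.tsv", sep="\t", index_label="subject_id")
        with pytest.raises(SchemaViolation):
            read_morphometry_table(tmp_path / "nan.tsv")
        loaded = read_morphometry_table(tmp_path / "nan.tsv", impute_missing=True)
        assert np.isfinite(loaded.values).all()

    def test_schema_counts(self):
        schema = default_morphometry_schema()
        roles = pd.Series(schema)
        assert (roles == "cortical_thickness").sum() == 68
        assert (roles == "subcortical_volume").sum() == 20
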