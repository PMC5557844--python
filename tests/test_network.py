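"""Pathway network assembly, PCC scoring, regulator overlays, exports."""

import numpy as np
import pandas as pd
import pytest

import stressdiel as sd
from stressdiel.errors import FormatError, ValidationError
from stressdiel.network import read_graphml_network, validate_interactions


def direct_pearson(x, y):
    """Covariance-over-sigmas formula, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)
    return cov / (x.std(ddof=1) * y.std(ddof=1))


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert sd.pearson(x, x) == pytest.approx(1.0)
        assert sd.pearson(x, -x) == pytest.approx(-1.0)

    def test_agrees_with_covariance_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert sd.pearson(x, y) == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_worked_example(self):
        x, y = (1, 2, 3, 4), (1, 2, 2, 4)
        assert sd.pearson(x, y) == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            sd.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            sd.pearson([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def synthetic_network_inputs():
    cfg = sd.SimConfig(n_genes=400, seed=19)
    interactions, anatomy = sd.generate_interactions(
        cfg, n_pathway_genes=11, n_partners=69, target_pcc=0.9
    )
    return cfg, interactions, sd.log2_normalize(anatomy)


class TestBuildNetwork:
    def test_edge_count_matches_interaction_records(self, synthetic_network_inputs):
        cfg, interactions, anatomy = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        assert net.n_edges == 69

    def test_isolated_pathway_genes_retained_as_nodes(self):
        interactions = pd.DataFrame(
            {"gene_a": ["p1"], "gene_b": ["x1"], "confidence": [0.8]}
        )
        net = sd.build_network(["p1", "p2", "p3"], interactions)
        assert net.n_nodes == 4  # p2, p3 isolated but present
        assert net.graph.degree("p2") == 0

    def test_threshold_one_flags_nothing(self, synthetic_network_inputs):
        cfg, interactions, anatomy = synthetic_network_inputs
        net = sd.build_network(
            cfg.gene_ids[:11], interactions, expression=anatomy, pcc_threshold=1.0
        )
        assert not net.edge_table()["high_pcc"].any()

    def test_planted_correlation_edges_flagged(self, synthetic_network_inputs):
        cfg, interactions, anatomy = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        edges = net.edge_table().set_index(["gene_a", "gene_b"])
        for row in interactions.dropna(subset=["target_pcc"]).itertuples():
            key = tuple(sorted((row.gene_a, row.gene_b)))
            assert edges.loc[key, "high_pcc"]

    def test_uncovered_edges_carry_no_pcc(self, synthetic_network_inputs):
        cfg, interactions, anatomy = synthetic_network_inputs
        trimmed = sd.ExpressionMatrix(
            anatomy.values.drop(index=interactions["gene_b"].iloc[0]), scale="log2"
        )
        net = sd.build_network(cfg.gene_ids[:11], interactions, expression=trimmed)
        edges = net.edge_table()
        first = interactions.iloc[0]
        key = tuple(sorted((first["gene_a"], first["gene_b"])))
        row = edges.set_index(["gene_a", "gene_b"]).loc[key]
        assert "pcc" not in row or pd.isna(row.get("pcc"))
        assert not row["high_pcc"]

    def test_empty_pathway_rejected(self, synthetic_network_inputs):
        _, interactions, _ = synthetic_network_inputs
        with pytest.raises(ValueError, match="empty pathway"):
            sd.build_network([], interactions)

    def test_rebuild_is_identical(self, synthetic_network_inputs):
        cfg, interactions, anatomy = synthetic_network_inputs
        a = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        b = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        pd.testing.assert_frame_equal(a.edge_table(), b.edge_table())
        pd.testing.assert_frame_equal(a.node_table(), b.node_table())


class TestValidateInteractions:
    def test_self_loops_and_duplicates_dropped(self):
        table = pd.DataFrame(
            {
                "gene_a": ["a", "a", "b", "c"],
                "gene_b": ["b", "a", "a", "d"],
                "confidence": [0.5, 0.9, 0.6, 0.7],
            }
        )
        clean = validate_interactions(table)
        assert len(clean) == 2  # a-a self-loop gone, b-a duplicate of a-b gone

    def test_confidence_outside_unit_interval_rejected(self):
        table = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "confidence": [1.5]}
        )
        with pytest.raises(ValidationError):
            validate_interactions(table)


class TestOverlayRegulator:
    @staticmethod
    def _regulators():
        return pd.DataFrame(
            {
                "regulator": ["OsbZIP23"] * 12,
                "target": [f"g{i:05d}" for i in range(1, 13)],
                "relation": ["bound"] * 11 + ["direct_target"],
            }
        )

    def test_bound_plus_target_records(self, synthetic_network_inputs):
        cfg, interactions, _ = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions)
        overlaid = sd.overlay_regulator(net, self._regulators())
        assert len(overlaid.regulator_edges) == 12
        assert "OsbZIP23" in overlaid.graph

    def test_empty_table_leaves_network_unchanged(self, synthetic_network_inputs):
        cfg, interactions, _ = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions)
        overlaid = sd.overlay_regulator(
            net, pd.DataFrame(columns=["regulator", "target", "relation"])
        )
        assert overlaid.n_nodes == net.n_nodes
        assert len(overlaid.regulator_edges) == 0

    def test_duplicates_collapsed(self, synthetic_network_inputs):
        cfg, interactions, _ = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions)
        doubled = pd.concat([self._regulators()] * 2)
        overlaid = sd.overlay_regulator(net, doubled)
        assert len(overlaid.regulator_edges) == 12

    def test_unknown_relation_rejected(self, synthetic_network_inputs):
        cfg, interactions, _ = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions)
        bad = pd.DataFrame(
            {"regulator": ["r"], "target": ["t"], "relation": ["inhibits"]}
        )
        with pytest.raises(FormatError, match="inhibits"):
            sd.overlay_regulator(net, bad)


class TestExport:
    def test_sif_line_count(self, tmp_path):
        interactions = pd.DataFrame(
            {"gene_a": ["a", "b"], "gene_b": ["b", "c"], "confidence": [0.5, 0.6]}
        )
        net = sd.build_network(["a"], interactions)
        written = sd.export_network(net, tmp_path, fmt="SIF")
        lines = written["sif"].read_text().splitlines()
        assert len(lines) == 2
        assert all("\tinteracts\t" in line for line in lines)

    def test_attribute_table_row_counts(self, synthetic_network_inputs, tmp_path):
        cfg, interactions, anatomy = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        written = sd.export_network(net, tmp_path, fmt="SIF")
        nodes = pd.read_csv(written["node_attributes"], sep="\t")
        edges = pd.read_csv(written["edge_attributes"], sep="\t")
        assert len(nodes) == net.n_nodes
        assert len(edges) == net.n_edges

    def test_graphml_round_trip_byte_identical(
        self, synthetic_network_inputs, tmp_path
    ):
        cfg, interactions, anatomy = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions, expression=anatomy)
        net = sd.overlay_regulator(
            net,
            pd.DataFrame(
                {
                    "regulator": ["OsbZIP23"],
                    "target": [cfg.gene_ids[0]],
                    "relation": ["bound"],
                }
            ),
        )
        first = sd.export_network(net, tmp_path / "a", fmt="GraphML")["graphml"]
        reread = read_graphml_network(first)
        second = sd.export_network(reread, tmp_path / "b", fmt="GraphML")["graphml"]
        assert first.read_bytes() == second.read_bytes()

    def test_unknown_format_rejected(self, synthetic_network_inputs, tmp_path):
        cfg, interactions, _ = synthetic_network_inputs
        net = sd.build_network(cfg.gene_ids[:11], interactions)
        with pytest.raises(ValueError, match="unknown export format"):
            sd.export_network(net, tmp_path, fmt="gexf")
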