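"""Entropy, homophily and egophily scores on labeled spatial graphs."""

import numpy as np
import pandas as pd
import pytest

from spatialhet.graph import build_delaunay_graph
from spatialhet.scores import (
    compute_all,
    egophily,
    global_entropy,
    global_homophily,
    local_entropy,
    local_homophily,
)
from spatialhet.experiments import naive_scores, random_labeled_graph

from conftest import cell_frame, make_graph


class TestGlobalScores:
    def test_entropy_single_type_is_zero(self):
        g = make_graph(
            edges=[("a", "b"), ("b", "c")],
            labels={"a": "A", "b": "A", "c": "A"},
            type_universe=["A", "B", "C"],
        )
        assert global_entropy(g) == 0.0

    def test_entropy_hand_computed_2_1_1(self):
        # p = (1/2, 1/4, 1/4) over |T|=3: H = 1.5*ln2 / ln3 = 0.9464
        g = make_graph(
            edges=[("a", "b"), ("b", "c"), ("c", "d")],
            labels={"a": "A", "b": "A", "c": "B", "d": "C"},
        )
        assert global_entropy(g) == pytest.approx(0.9464, abs=1e-4)

    def test_entropy_uniform_is_one(self):
        g = make_graph(
            edges=[("a", "b"), ("b", "c")],
            labels={"a": "A", "b": "B", "c": "C"},
        )
        assert global_entropy(g) == pytest.approx(1.0)

    def test_entropy_degenerate_universe_of_one(self):
        g = make_graph(edges=[("a", "b"), ("b", "c")], labels={k: "A" for k in "abc"})
        assert global_entropy(g) == 0.0

    def test_homophily_path_half(self):
        g = make_graph(edges=[("a", "b"), ("b", "c")], labels={"a": "A", "b": "A", "c": "B"})
        assert global_homophily(g) == pytest.approx(0.5)

    def test_homophily_monochromatic_is_one(self, path_aabb):
        g = make_graph(edges=[("a", "b"), ("b", "c")], labels={k: "A" for k in "abc"})
        assert global_homophily(g) == 1.0

    def test_homophily_bipartite_is_zero(self):
        edges = [(f"a{i}", f"b{j}") for i in range(2) for j in range(2)]
        labels = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        assert global_homophily(make_graph(edges, labels)) == 0.0

    def test_edgeless_homophily_is_error(self):
        g = make_graph(edges=[], labels={"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="edgeless"):
            global_homophily(g)


class TestLocalScores:
    def test_star_hub_entropy_hand_computed(self, star_graph):
        # hub sees p=(1/4, 3/4): H = 0.8113 in base |T|=2
        assert local_entropy(star_graph, 1)["hub"] == pytest.approx(0.8113, abs=1e-4)

    def test_star_egophily_hub_quarter_leaf_half(self, star_graph):
        ego = egophily(star_graph, 1)
        assert ego["hub"] == pytest.approx(0.25)
        assert ego["l1"] == pytest.approx(0.5)

    def test_star_hub_local_homophily_zero(self, star_graph):
        assert local_homophily(star_graph, 1)["hub"] == 0.0

    def test_path_aabb_center_homophily_half(self, path_aabb):
        # N_1(b) = {a,b,c}; induced edges (a,b) mono, (b,c) not
        assert local_homophily(path_aabb, 1)["b"] == pytest.approx(0.5)

    def test_single_type_neighborhood_zero_entropy(self, path_aabb):
        # N_1(a) = {a,b}, both A
        assert local_entropy(path_aabb, 1)["a"] == 0.0

    def test_radius_beyond_diameter_equals_global(self, path_aabb):
        ge, gh = global_entropy(path_aabb), global_homophily(path_aabb)
        for c in path_aabb.cell_ids:
            assert local_entropy(path_aabb, 9)[c] == pytest.approx(ge)
            assert local_homophily(path_aabb, 9)[c] == pytest.approx(gh)

    def test_egophily_lower_bound_self_inclusion(self):
        rng = np.random.default_rng(0)
        g = random_labeled_graph(rng)
        hoods = egophily(g, 2)
        sizes = {c: len(v) for c, v in zip(g.cell_ids, g.adjacency.toarray())}
        assert all(v > 0 for v in hoods.values())

    def test_missing_homophily_only_for_empty_induced_edges(self):
        # isolated vertex: N_r = {v}, no induced edges -> NaN
        g = make_graph(edges=[("a", "b")], labels={"a": "A", "b": "A", "c": "B"})
        hom = local_homophily(g, 1)
        assert np.isnan(hom["c"])
        assert hom["a"] == 1.0

    def test_label_bijection_invariance(self):
        rng = np.random.default_rng(4)
        g = random_labeled_graph(rng)
        swapped = {t: s for t, s in zip(g.type_universe, reversed(g.type_universe))}
        g2 = make_graph(
            edges=[tuple(sorted(e)) for e in g.edge_list()],
            labels={c: swapped[l] for c, l in zip(g.cell_ids, g.labels)},
            type_universe=g.type_universe,
        )
        for r in (1, 2):
            a = local_entropy(g, r)
            b = local_entropy(g2, r)
            for c in g.cell_ids:
                assert a[c] == pytest.approx(b[c], abs=1e-12)
        assert global_entropy(g) == pytest.approx(global_entropy(g2), abs=1e-12)
        assert global_homophily(g) == pytest.approx(global_homophily(g2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        g = random_labeled_graph(rng)
        ref = naive_scores(g, 2)
        ent = local_entropy(g, 2)
        hom = local_homophily(g, 2)
        ego = egophily(g, 2)
        for i, c in enumerate(g.cell_ids):
            assert ent[c] == pytest.approx(ref["local_entropy"][i], abs=1e-12)
            assert ego[c] == pytest.approx(ref["egophily"][i], abs=1e-12)
            if np.isnan(ref["local_homophily"][i]):
                assert np.isnan(hom[c])
            else:
                assert hom[c] == pytest.approx(ref["local_homophily"][i], abs=1e-12)


class TestComputeAll:
    @pytest.fixture
    def toy_cohort(self):
        rng = np.random.default_rng(9)
        frames = []
        for s in ("S1", "S2"):
            pts = rng.uniform(0, 50, size=(12, 2))
            f = cell_frame(
                [tuple(p) for p in pts],
                sample_id=s,
                condition="X" if s == "S1" else "Y",
                cell_types=list(rng.choice(["A", "B"], size=12)),
            )
            f["cell_id"] = s + "_" + f["cell_id"]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_row_count_arithmetic(self, toy_cohort):
        table = compute_all(toy_cohort, radii=[1, 2])
        assert len(table) == 2 * 2 + 3 * 2 * 24

    def test_order_invariance(self, toy_cohort):
        a = compute_all(toy_cohort, radii=[1])
        b = compute_all(toy_cohort.sample(frac=1, random_state=1), radii=[1])
        pd.testing.assert_frame_equal(a, b)

    def test_values_match_single_score_calls(self, toy_cohort):
        table = compute_all(toy_cohort, radii=[2])
        universe = table.attrs["type_universe"]
        sub = toy_cohort[toy_cohort["sample_id"] == "S1"]
        g = build_delaunay_graph(sub, type_universe=universe)
        ent = local_entropy(g, 2)
        rows = table[
            (table["sample_id"] == "S1") & (table["score"] == "local_entropy")
        ].set_index("cell_id")["value"]
        for c, v in ent.items():
            assert rows[c] == pytest.approx(v, abs=1e-12)
        grow = table[(table["sample_id"] == "S1") & (table["score"] == "global_entropy")]
        assert grow["value"].iloc[0] == pytest.approx(global_entropy(g), abs=1e-12)

    def test_bad_sample_skipped_with_report(self, toy_cohort):
        bad = pd.DataFrame(
            {
                "cell_id": ["z1", "z2"],
                "x": [0, 1],
                "y": [0, 0],
                "sample_id": "S3",
                "condition": "X",
                "cell_type": "A",
            }
        )
        table = compute_all(pd.concat([toy_cohort, bad], ignore_index=True), radii=[1])
        assert [s for s, _ in table.attrs["skipped_samples"]] == ["S3"]
        assert set(table["sample_id"]) == {"S1", "S2"}

    def test_values_lie_in_unit_interval(self, toy_cohort):
        table = compute_all(toy_cohort, radii=[1, 3])
        vals = table["value"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_unknown_cells_can_be_excluded(self, toy_cohort):
        toy = toy_cohort.copy()
        toy.loc[toy.index[:4], "cell_type"] = "unknown"
        with_unknown = compute_all(toy, radii=[1])
        without = compute_all(toy, radii=[1], include_unknown=False)
        assert "unknown" in with_unknown.attrs["type_universe"]
        assert "unknown" not in without.attrs["type_universe"]
        assert set(without["cell_id"].dropna()) == set(
            toy.loc[toy["cell_type"] != "unknown", "cell_id"]
        )

    def test_missing_cell_type_rejected(self, toy_cohort):
        toy = toy_cohort.copy()
        toy.loc[0, "cell_type"] = np.nan
        with pytest.raises(ValueError, match="cell_type"):
            compute_all(toy, radii=[1])
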