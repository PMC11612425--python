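"""Reference aggregation, spread scores, bimodality gating, type assignment."""

import numpy as np
import pandas as pd
import pytest

from spatialhet.celltypes import (
    ReferenceExpression,
    ReferenceError,
    aggregate_reference,
    assign_cell_types,
    check_separation,
    fit_bimodal,
    load_reference,
    match_genes,
    sorted_candidates,
    spread_scores,
)
from spatialhet.simulate import TissueSimConfig, simulate_reference, reference_to_hpa_frames


def ref_frames(values, sizes):
    """values: {cluster: {gene: x}}, sizes: {cluster: (cell_type, size)}."""
    rows = [
        {"cluster": c, "gene": g, "expression": x}
        for c, genes in values.items()
        for g, x in genes.items()
    ]
    ann = [{"cluster": c, "cell_type": t, "size": s} for c, (t, s) in sizes.items()]
    return pd.DataFrame(rows), pd.DataFrame(ann)


class TestAggregateReference:
    def test_size_weighted_mean(self):
        clusters, ann = ref_frames(
            {"c1": {"g": 2.0}, "c2": {"g": 6.0}},
            {"c1": ("T", 10), "c2": ("T", 30)},
        )
        x = aggregate_reference(clusters, ann)
        assert x.loc["T", "g"] == pytest.approx(5.0)

    def test_single_cluster_passthrough(self):
        clusters, ann = ref_frames({"c1": {"g": 3.7}}, {"c1": ("T", 5)})
        assert aggregate_reference(clusters, ann).loc["T", "g"] == pytest.approx(3.7)

    def test_equal_sizes_is_plain_mean(self):
        clusters, ann = ref_frames(
            {"c1": {"g": 1.0}, "c2": {"g": 3.0}},
            {"c1": ("T", 7), "c2": ("T", 7)},
        )
        assert aggregate_reference(clusters, ann).loc["T", "g"] == pytest.approx(2.0)

    def test_nonpositive_size_rejected(self):
        clusters, ann = ref_frames({"c1": {"g": 1.0}}, {"c1": ("T", 0)})
        with pytest.raises(ReferenceError, match="positive"):
            aggregate_reference(clusters, ann)

    def test_aggregate_within_cluster_range(self):
        rng = np.random.default_rng(1)
        vals = {f"c{i}": {"g": float(rng.uniform(0, 10))} for i in range(5)}
        sizes = {f"c{i}": ("T", int(rng.integers(1, 100))) for i in range(5)}
        clusters, ann = ref_frames(vals, sizes)
        x = aggregate_reference(clusters, ann).loc["T", "g"]
        raw = [v["g"] for v in vals.values()]
        assert min(raw) <= x <= max(raw)


class TestSpreadScores:
    def test_direct_evaluation(self):
        x = pd.DataFrame({"g": [5.0, 1.0, 0.0]}, index=["t1", "t2", "t3"])
        s = spread_scores(x, ["t1", "t2", "t3"])
        assert s.loc["t1", "g"] == pytest.approx(4.0)
        assert s.loc["t2", "g"] == pytest.approx(-4.0)
        assert s.loc["t3", "g"] == pytest.approx(-5.0)

    def test_symmetric_tie_gives_zero(self):
        x = pd.DataFrame({"g": [2.0, 2.0]}, index=["t1", "t2"])
        s = spread_scores(x, ["t1", "t2"])
        assert (s["g"] == 0.0).all()

    def test_removing_runner_up_weakly_increases(self):
        x = pd.DataFrame({"g": [5.0, 4.0, 1.0]}, index=["t1", "t2", "t3"])
        before = spread_scores(x, ["t1", "t2", "t3"]).loc["t1", "g"]
        after = spread_scores(x, ["t1", "t3"]).loc["t1", "g"]
        assert after >= before

    def test_single_type_undefined(self):
        x = pd.DataFrame({"g": [5.0]}, index=["t1"])
        with pytest.raises(ValueError, match="two"):
            spread_scores(x, ["t1"])

    def test_candidate_sort_is_deterministic_on_ties(self):
        x = pd.DataFrame({"ga": [3.0, 0.0], "gb": [3.0, 0.0]}, index=["t2", "t1"])
        cands = sorted_candidates(spread_scores(x, ["t1", "t2"]))
        assert cands[:2] == [("t2", "ga"), ("t2", "gb")]


class TestBimodalityGate:
    def test_separation_condition_examples(self):
        assert check_separation(0.1, 0.02, 0.6, 0.1)      # 0.1392 < 0.404
        assert not check_separation(0.3, 0.1, 0.5, 0.1)   # 0.496 < 0.304 fails

    def test_parameter_recovery_on_simulated_mixture(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(0.05, 0.01, 1000), rng.normal(0.8, 0.05, 1000)]
        )
        fit = fit_bimodal(vals, seed=0)
        assert fit.good
        assert fit.mu0 == pytest.approx(0.05, abs=0.02)
        assert fit.mu1 == pytest.approx(0.8, abs=0.02)

    def test_constant_values_not_good(self):
        fit = fit_bimodal(np.full(100, 0.4), seed=0)
        assert not fit.good

    def test_unimodal_values_not_good(self):
        rng = np.random.default_rng(1)
        fit = fit_bimodal(rng.uniform(0.2, 0.3, 500), seed=0)
        assert not fit.good


def designed_abundance(rng, n_per_type, types, markers, markerless=0):
    """Bimodal abundance: own marker uniform high, others near zero."""
    rows, truth = [], []
    for t in types:
        for _ in range(n_per_type):
            row = {m: rng.uniform(0.0, 0.03) for m in markers.values()}
            row[markers[t]] = rng.uniform(0.85, 0.95)
            rows.append(row)
            truth.append(t)
    for _ in range(markerless):
        rows.append({m: rng.uniform(0.0, 0.03) for m in markers.values()})
        truth.append("unknown")
    idx = [f"cell{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(truth, index=idx)


@pytest.fixture
def designed_reference():
    types = ["alpha", "beta", "gamma"]
    markers = {t: f"G-{t}" for t in types}
    values, sizes = {}, {}
    ci = 0
    for t in types + ["spare"]:  # 'spare' absorbs the final-iteration stop
        for j in range(2):
            c = f"c{ci}"
            ci += 1
            values[c] = {m: (8.0 if (t != "spare" and m == markers[t]) else 0.3)
                         for m in markers.values()}
            sizes[c] = (t, 10 * (j + 1))
    clusters, ann = ref_frames(values, sizes)
    return types, markers, ReferenceExpression(clusters=clusters, annotations=ann)


class TestAssignment:
    def test_recovery_on_designed_bimodal_abundance(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(5)
        abundance, truth = designed_abundance(rng, 80, types, markers, markerless=10)
        labels, log = assign_cell_types(abundance, ref, seed=0)
        known = truth != "unknown"
        assert (labels[known] == truth[known]).all()
        assert (labels[~known] == "unknown").all()
        assert len(log) == len(types)

    def test_all_unimodal_means_zero_iterations_all_unknown(self, designed_reference):
        _, markers, ref = designed_reference
        rng = np.random.default_rng(6)
        abundance = pd.DataFrame(
            {m: rng.uniform(0.2, 0.25, 50) for m in markers.values()},
            index=[f"c{i}" for i in range(50)],
        )
        labels, log = assign_cell_types(abundance, ref, seed=0)
        assert log == []
        assert (labels == "unknown").all()

    def test_stops_when_surviving_pool_is_unimodal(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(7)
        # only alpha and beta present: alpha is assigned first, after which
        # the all-beta pool is unimodal on every gene -> no good gene -> stop
        abundance, truth = designed_abundance(rng, 60, ["alpha", "beta"], markers)
        labels, log = assign_cell_types(abundance, ref, seed=0)
        assert len(log) == 1
        assert (labels[truth == "alpha"] == "alpha").all()
        assert (labels[truth == "beta"] == "unknown").all()

    def test_terminates_within_type_count_iterations(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(17)
        abundance, _ = designed_abundance(rng, 50, types, markers, markerless=20)
        _, log = assign_cell_types(abundance, ref, seed=0)
        assert len(log) <= len(ref.types)

    def test_empty_pool_exits_with_types_remaining(self, designed_reference):
        _, markers, ref = designed_reference
        abundance = pd.DataFrame(columns=list(markers.values()))
        labels, log = assign_cell_types(abundance, ref, seed=0)
        assert log == []
        assert len(labels) == 0

    def test_row_order_does_not_change_labels(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(8)
        abundance, _ = designed_abundance(rng, 40, types, markers)
        a, _ = assign_cell_types(abundance, ref, seed=0)
        b, _ = assign_cell_types(abundance.sample(frac=1, random_state=3), ref, seed=0)
        assert a.sort_index().equals(b.sort_index())

    def test_partition_property(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(9)
        abundance, _ = designed_abundance(rng, 30, types, markers, markerless=5)
        labels, _ = assign_cell_types(abundance, ref, seed=0)
        assert set(labels.index) == set(abundance.index)
        assert labels.notna().all()

    def test_audit_log_threshold_matches_fit(self, designed_reference):
        types, markers, ref = designed_reference
        rng = np.random.default_rng(10)
        abundance, _ = designed_abundance(rng, 50, types, markers)
        _, log = assign_cell_types(abundance, ref, seed=0)
        for entry in log:
            assert entry["threshold"] == pytest.approx(
                entry["mu1"] - 1.96 * entry["sigma1"]
            )

    def test_no_gene_overlap_is_error(self, designed_reference):
        _, _, ref = designed_reference
        abundance = pd.DataFrame({"XYZ": [0.1, 0.9]}, index=["a", "b"])
        with pytest.raises(ReferenceError, match="overlap"):
            assign_cell_types(abundance, ref)

    def test_synonym_map_routes_protein_names(self, designed_reference):
        _, markers, ref = designed_reference
        mapping = match_genes(
            pd.DataFrame(columns=["CD-ALPHA"]),
            ref.genes,
            synonym_map={"CD-ALPHA": "G-alpha"},
        )
        assert mapping == {"CD-ALPHA": "G-alpha"}


class TestReferenceIO:
    def test_hpa_dialect_round_trip(self, tmp_path):
        cfg = TissueSimConfig(seed=4)
        ref = simulate_reference(cfg)
        expr, desc = reference_to_hpa_frames(ref)
        p1, p2 = tmp_path / "expr.tsv", tmp_path / "desc.tsv"
        expr.to_csv(p1, sep="\t", index=False)
        desc.to_csv(p2, sep="\t", index=False)
        loaded = load_reference(p1, p2, tissue="skin")
        pd.testing.assert_frame_equal(
            loaded.type_expression, ref.type_expression, check_like=True
        )
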