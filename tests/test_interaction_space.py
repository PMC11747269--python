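"""Correlation-space fitting, threshold calibration, and edge prediction."""

import numpy as np
import pytest

from herbsynergy.interaction_space import (DescriptorMatrix, InteractionEdge,
                                           calibrate_thresholds, fit_space,
                                           ligand_threshold, merge_networks,
                                           predict_interactions)
from herbsynergy.synthetic import SynthConfig, gen_descriptor_world


def _matrix(values, kind, prefix):
    values = np.asarray(values, dtype=float)
    return DescriptorMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                            values,
                            [f"{prefix}d{j}" for j in range(values.shape[1])],
                            kind)


@pytest.fixture()
def target_matrix():
    rng = np.random.default_rng(0)
    return _matrix(rng.normal(size=(6, 5)), "target", "t")


class TestFitSpace:
    def test_isotropic_data_needs_all_dims_for_full_variance(self, target_matrix):
        rng = np.random.default_rng(1)
        comp = _matrix(rng.normal(size=(200, 3)), "compound", "c")
        space = fit_space(comp, target_matrix, variance_target=1.0)
        assert space.retained_dims[0] == 3

    def test_dominant_direction_needs_one_dim(self, target_matrix):
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        X = np.column_stack([base, 2 * base + 1e-3 * rng.normal(size=200),
                             -base + 1e-3 * rng.normal(size=200)])
        space = fit_space(_matrix(X, "compound", "c"), target_matrix,
                          variance_target=0.9)
        assert space.retained_dims[0] == 1
        assert space.compound_block.variance_fraction > 0.99

    def test_standardization_idempotent(self, target_matrix):
        rng = np.random.default_rng(3)
        X = rng.normal(loc=5.0, scale=3.0, size=(50, 4))
        space = fit_space(_matrix(X, "compound", "c"), target_matrix,
                          variance_target=1.0)
        Z = space.compound_block.standardize(X)
        space2 = fit_space(_matrix(Z, "compound", "c"), target_matrix,
                           variance_target=1.0)
        assert np.allclose(space2.compound_block.standardize(Z), Z, atol=1e-12)

    def test_projection_back_rotation_reconstructs_standardized_data(
            self, target_matrix):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        space = fit_space(_matrix(X, "compound", "c"), target_matrix,
                          variance_target=1.0)
        block = space.compound_block
        Z = block.standardize(X)
        assert np.allclose(block.project(X) @ block.components, Z, atol=1e-8)

    def test_requested_dims_shrink_to_rank_with_warning(self, target_matrix):
        rng = np.random.default_rng(5)
        comp = _matrix(rng.normal(size=(4, 10)), "compound", "c")
        with pytest.warns(UserWarning, match="rank"):
            space = fit_space(comp, target_matrix, n_components=(42, 3))
        assert space.retained_dims[0] <= 3

    def test_zero_variance_descriptors_dropped(self, target_matrix):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, np.full(30, 7.0)])  # constant column
        space = fit_space(_matrix(X, "compound", "c"), target_matrix,
                          variance_target=1.0)
        assert space.compound_block.kept_columns.tolist() == [0, 1, 2]


class TestLigandThreshold:
    def test_degenerate_equal_distances(self):
        assert ligand_threshold(np.full(10, 2.5)) == pytest.approx(2.5)

    def test_matches_brute_force_order_statistic(self):
        d = np.arange(1.0, 101.0)
        # linear-interpolation quantile at h = 0.95 * (n - 1)
        h = 0.95 * 99
        lo = int(np.floor(h))
        expected = d[lo] + (h - lo) * (d[lo + 1] - d[lo])
        assert ligand_threshold(d) == pytest.approx(expected)
        assert expected == pytest.approx(95.05)

    def test_monotone_in_spread(self):
        rng = np.random.default_rng(0)
        d = rng.random(50)
        assert ligand_threshold(2.0 * d) >= ligand_threshold(d)


@pytest.fixture(scope="module")
def small_world():
    cfg = SynthConfig(seed=11, n_compounds=120, n_targets=5,
                      extra_ligand_fraction=0.8)
    compounds, targets, edges = gen_descriptor_world(cfg)
    space = fit_space(compounds, targets, variance_target=0.99)
    space = calibrate_thresholds(space, edges)
    return compounds, targets, edges, space


class TestCalibrateAndPredict:
    def test_thresholds_positive_for_every_known_target(self, small_world):
        *_, edges, space = small_world
        assert set(space.thresholds) == {t for _, t in edges}
        assert all(v > 0 for v in space.thresholds.values())

    def test_single_ligand_target_uses_flagged_global_fallback(self):
        cfg = SynthConfig(seed=3, n_compounds=40, n_targets=4,
                          extra_ligand_fraction=0.7)
        compounds, targets, edges = gen_descriptor_world(cfg)
        # strip target T000 down to a single known ligand
        kept, seen = [], False
        for c, t in sorted(edges):
            if t == "T000" and seen:
                continue
            seen = seen or t == "T000"
            kept.append(InteractionEdge(c, t, "known"))
        space = fit_space(compounds, targets, variance_target=0.99)
        space = calibrate_thresholds(space, kept)
        assert "T000" in space.fallback_targets
        assert space.thresholds["T000"] > 0

    def test_compound_at_centroid_gets_zero_distance_edge(self, small_world):
        compounds, _, _, space = small_world
        target = sorted(space.centroids)[0]
        block = space.compound_block
        z = space.centroids[target] @ block.components
        raw = np.zeros(compounds.values.shape[1])
        raw[block.kept_columns] = z * block.sd + block.mean
        probe = DescriptorMatrix(["probe"], raw[None, :], compounds.columns,
                                 "compound")
        edges = predict_interactions(space, probe)
        hit = {(e.compound, e.target): e for e in edges}[("probe", target)]
        assert hit.distance == pytest.approx(0.0, abs=1e-8)

    def test_compound_at_twice_threshold_not_linked(self, small_world):
        compounds, _, _, space = small_world
        target = sorted(space.centroids)[0]
        block = space.compound_block
        direction = np.zeros_like(space.centroids[target])
        direction[0] = 1.0
        pos = space.centroids[target] + 2.0 * space.thresholds[target] * direction
        raw = np.zeros(compounds.values.shape[1])
        raw[block.kept_columns] = (pos @ block.components) * block.sd + block.mean
        probe = DescriptorMatrix(["probe"], raw[None, :], compounds.columns,
                                 "compound")
        edges = predict_interactions(space, probe)
        assert ("probe", target) not in {(e.compound, e.target) for e in edges}

    def test_unprojectable_compound_excluded_with_warning(self, small_world):
        compounds, *_ , space = small_world
        bad = np.full((1, compounds.values.shape[1]), np.nan)
        probe = DescriptorMatrix(["bad"], bad, compounds.columns, "compound")
        with pytest.warns(UserWarning, match="bad"):
            edges = predict_interactions(space, probe)
        assert not edges

    def test_held_out_recall_at_least_point_nine(self):
        cfg = SynthConfig(seed=7, n_compounds=400, n_targets=8,
                          extra_ligand_fraction=0.85)
        compounds, targets, edges = gen_descriptor_world(cfg)
        by_target = {}
        for c, t in sorted(edges):
            by_target.setdefault(t, []).append(c)
        calib, heldout = [], []
        for t, members in by_target.items():
            k = max(2, (2 * len(members)) // 3)
            calib += [(c, t) for c in members[:k]]
            heldout += [(c, t) for c in members[k:]]
        space = fit_space(compounds, targets, variance_target=0.99)
        space = calibrate_thresholds(space, calib)
        predicted = {(e.compound, e.target)
                     for e in predict_interactions(space, compounds)}
        recall = sum(e in predicted for e in heldout) / len(heldout)
        assert recall >= 0.9


class TestMergeNetworks:
    def test_disjoint_union(self):
        known = {InteractionEdge(f"c{i}", "t1", "known") for i in range(3)}
        pred = {InteractionEdge(f"c{i}", "t2", "predicted", 0.1)
                for i in range(4)}
        edges, summary = merge_networks(known, pred)
        assert summary["n_edges"] == 7

    def test_duplicate_collapses_to_known_and_keeps_distance(self):
        known = {InteractionEdge("c1", "t1", "known")}
        pred = {InteractionEdge("c1", "t1", "predicted", 0.25)}
        edges, summary = merge_networks(known, pred)
        assert summary["n_edges"] == 1
        (edge,) = edges
        assert edge.provenance == "known"
        assert edge.distance == 0.25

    def test_expanded_network_summary_counts(self):
        """A network of 27 compounds, 373 targets and 1,577 edges reports
        exactly those cardinalities (round-trip, not a recomputation)."""
        pairs = {(c, c % 373) for c in range(27)}
        pairs |= {(t % 27, t) for t in range(373)}
        c, t = 0, 0
        while len(pairs) < 1577:
            pairs.add((c % 27, (c * 7 + t) % 373))
            c, t = c + 1, t + 3
        edges = {InteractionEdge(f"c{c}", f"t{t}", "known") for c, t in pairs}
        _, summary = merge_networks(edges, set())
        assert (summary["n_compounds"], summary["n_targets"],
                summary["n_edges"]) == (27, 373, 1577)
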