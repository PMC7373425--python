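import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from acini3d.cluster_id import Cluster, identify_clusters
from acini3d.errors import DataError, DegenerateGeometryError
from acini3d.feature_extraction import (
    FEATURE_NAMES,
    ContactRule,
    acinus_geometry,
    acinus_summaries,
    annotate_outcomes,
    cluster_volume_membership,
    compute_features,
    compute_features_cohort,
    contact_count,
)
from acini3d.io_tables import CohortTable
from acini3d.synthetic_acini import SyntheticConfig, generate_cohort
from conftest import make_cells


def _cluster(cells, member_idx, acinus_id="a1", cluster_id="cluster_0"):
    members = [cells.iloc[i]["cell_id"] for i in member_idx]
    sub = cells[cells["cell_id"].isin(members)]
    coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
    from scipy.spatial.distance import pdist

    diam = 0.0 if len(coords) < 2 else float(pdist(coords).max())
    return Cluster(acinus_id, cluster_id, sorted(members), coords.mean(axis=0), diam)


class TestAcinusGeometry:
    def test_density_formula(self):
        # 4 cells, most distant pair 10 µm apart -> density 4/(100*pi)
        cells = make_cells(
            [(0, 0, 0), (10, 0, 0), (5, 1, 0), (5, -1, 0)], [False] * 4
        )
        n, dmax, surface, density = acinus_geometry(cells)
        assert (n, dmax) == (4, pytest.approx(10.0))
        assert surface == pytest.approx(math.pi * 100)
        assert density == pytest.approx(4 / (math.pi * 100), rel=1e-9)
        assert density == pytest.approx(0.012732, rel=1e-4)

    def test_coincident_cells_degenerate(self):
        cells = make_cells([(1, 1, 1), (1, 1, 1)], [False, False])
        with pytest.raises(DegenerateGeometryError):
            acinus_geometry(cells)

    def test_single_cell_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            acinus_geometry(make_cells([(0, 0, 0)], [False]))

    def test_dmax_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 60, size=(12, 3))
        cells = make_cells(coords, [False] * 12)
        _, dmax, _, _ = acinus_geometry(cells)
        brute = max(
            np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            for i in range(12)
            for j in range(12)
        )
        assert dmax == pytest.approx(brute, abs=1e-12)


class TestClusterVolume:
    def test_midpoint_cell_inside_two_member_ball(self):
        cells = make_cells(
            [(0, 0, 0), (10, 0, 0), (5, 0, 0)], [True, True, False]
        )
        cluster = _cluster(cells, [0, 1])
        assert cluster_volume_membership(cluster, cells) == {"c000", "c001", "c002"}

    def test_singleton_ball_contains_only_member(self):
        cells = make_cells([(0, 0, 0), (8, 0, 0)], [True, False])
        cluster = _cluster(cells, [0])
        assert cluster_volume_membership(cluster, cells) == {"c000"}

    def test_equilateral_members_fall_outside_their_own_volume(self):
        # vertices of an equilateral triangle of side D sit at D/sqrt(3) > D/2
        # from the centroid, so the members themselves are outside the ball
        D = 12.0
        coords = [
            (0, 0, 0),
            (D, 0, 0),
            (D / 2, D * math.sqrt(3) / 2, 0),
        ]
        cells = make_cells(coords, [True] * 3)
        cluster = _cluster(cells, [0, 1, 2])
        assert cluster_volume_membership(cluster, cells) == set()

    def test_ball_membership_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            coords = rng.uniform(0, 40, size=(n, 3))
            transduced = rng.random(n) < 0.5
            transduced[:2] = True
            cells = make_cells(coords, transduced)
            member_idx = list(np.where(transduced)[0][:3])
            cluster = _cluster(cells, member_idx)
            got = cluster_volume_membership(cluster, cells)
            center = coords[member_idx].mean(axis=0)
            radius = cluster.sphere_diameter / 2
            brute = {
                cells.iloc[i]["cell_id"]
                for i in range(n)
                if np.sqrt(((coords[i] - center) ** 2).sum()) <= radius + 1e-12
            }
            if radius == 0:
                brute |= set(cluster.members)
            assert got == brute


class TestContacts:
    RULE = ContactRule(mean_diameter=10.0, sd_diameter=1.0)  # threshold 12

    def test_pair_just_below_threshold_counts(self):
        cells = make_cells([(0, 0, 0), (11.9, 0, 0)], [True, True])
        assert contact_count(_cluster(cells, [0, 1]), cells, self.RULE) == 1

    def test_pair_exactly_at_threshold_does_not_count(self):
        # the contact rule is strict: "less than" the threshold
        cells = make_cells([(0, 0, 0), (12.0, 0, 0)], [True, True])
        assert contact_count(_cluster(cells, [0, 1]), cells, self.RULE) == 0

    def test_complete_quadruple_has_six_contacts(self):
        coords = [(0, 0, 0), (5, 0, 0), (0, 5, 0), (0, 0, 5)]
        cells = make_cells(coords, [True] * 4)
        assert contact_count(_cluster(cells, [0, 1, 2, 3]), cells, self.RULE) == 6

    def test_rule_estimated_from_diameter_column(self):
        cells = make_cells([(0, 0, 0), (30, 0, 0)], [True, True], diameter=[8.0, 12.0])
        rule = ContactRule.from_cells(cells)
        assert rule.mean_diameter == pytest.approx(10.0)
        assert rule.threshold == pytest.approx(10.0 + 2 * np.std([8, 12], ddof=1))


class TestComputeFeatures:
    def test_singleton_conventions(self):
        cells = make_cells(
            [(0, 0, 0), (20, 0, 0), (0, 20, 0)], [True, False, False]
        )
        rows = compute_features(cells, [_cluster(cells, [0])])
        r = rows.iloc[0]
        assert r["n_transduced_in_cluster"] == 1
        assert r["mean_pairwise_dist_volume"] == 0.0
        assert r["mean_pairwise_dist_transduced"] == 0.0
        assert r["n_contacts_transduced"] == 0
        assert r["n_cells_in_cluster_volume"] == 1
        assert r["fraction_transduced_in_volume"] == 1.0

    def test_two_member_cluster_hand_computed(self):
        # members 10 µm apart, no other cell in the ball, threshold 12
        cells = make_cells(
            [(0, 0, 0), (10, 0, 0), (30, 0, 0)], [True, True, False]
        )
        rule = ContactRule(10.0, 1.0)
        rows = compute_features(cells, [_cluster(cells, [0, 1])], rule)
        r = rows.iloc[0]
        assert r["n_cells_in_cluster_volume"] == 2
        assert r["n_transduced_in_cluster"] == 2
        assert r["mean_pairwise_dist_volume"] == pytest.approx(10.0)
        assert r["mean_pairwise_dist_transduced"] == pytest.approx(10.0)
        assert r["fraction_transduced_in_volume"] == 1.0
        assert r["n_contacts_transduced"] == 1

    def test_invariants_hold_on_synthetic_cohort(self):
        cohort, _, _ = generate_cohort(SyntheticConfig(n_acini=25, seed=3))
        clusters = identify_clusters(cohort)
        feats = compute_features_cohort(cohort, clusters)
        assert len(feats) > 40
        f = feats
        assert (f["n_transduced_in_cluster"] <= f["n_transduced_acinus"]).all()
        assert (f["n_transduced_acinus"] <= f["n_cells_acinus"]).all()
        assert (f["n_cells_in_cluster_volume"] >= 1).all()
        assert f["fraction_transduced_in_volume"].between(0, 1).all()
        m = f["n_transduced_in_cluster"]
        assert (f["n_contacts_transduced"] <= m * (m - 1) / 2).all()
        assert (f[["mean_pairwise_dist_volume", "mean_pairwise_dist_transduced"]] >= 0).all().all()

    def test_rigid_motion_invariance(self, rng):
        cohort, _, _ = generate_cohort(SyntheticConfig(n_acini=2, seed=9))
        clusters = identify_clusters(cohort)
        rule = ContactRule(10.0, 1.0)
        feats = compute_features_cohort(cohort, clusters, rule=rule)
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([37.0, -11.0, 4.0])
        moved = cohort.cells.copy()
        moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() @ rot.T + shift
        cohort2 = CohortTable(moved)
        clusters2 = identify_clusters(cohort2)
        feats2 = compute_features_cohort(cohort2, clusters2, rule=rule)
        pd.testing.assert_frame_equal(
            feats.drop(columns="outcome"), feats2.drop(columns="outcome"),
            rtol=1e-9, atol=1e-9,
        )


class TestOutcomes:
    def _clusters(self):
        cells = make_cells(
            [(0, 0, 0), (5, 0, 0), (80, 0, 0)], [True, True, True]
        )
        return {
            "a1": [
                _cluster(cells, [0, 1], cluster_id="cluster_0"),
                _cluster(cells, [2], cluster_id="cluster_1"),
            ]
        }

    def test_explicit_annotations_copied(self):
        ann = pd.DataFrame(
            {
                "acinus_id": ["a1", "a1"],
                "cluster_id": ["cluster_0", "cluster_1"],
                "tumor": [True, False],
            }
        )
        clusters = annotate_outcomes(self._clusters(), annotations=ann)
        assert [c.tumor for c in clusters["a1"]] == [True, False]

    def test_missing_annotation_errors(self):
        ann = pd.DataFrame(
            {"acinus_id": ["a1"], "cluster_id": ["cluster_0"], "tumor": [True]}
        )
        with pytest.raises(DataError, match="cluster_1"):
            annotate_outcomes(self._clusters(), annotations=ann)

    def test_lineage_fold_expansion_rule(self):
        # one member expanded 1 -> 8 (>= 4-fold): tumor; quiescent: no tumor
        lineage = pd.DataFrame(
            {
                "acinus_id": ["a1", "a1", "a1"],
                "cell_id": ["c000", "c001", "c002"],
                "n_end": [8, 1, 1],
            }
        )
        clusters = annotate_outcomes(self._clusters(), lineage=lineage)
        assert [c.tumor for c in clusters["a1"]] == [True, False]


class TestAcinusSummaries:
    def _cohorts(self):
        start_frames, end_frames = [], []
        rng = np.random.default_rng(2)
        for i, (n_s, n_e, tr_s, tr_e) in enumerate(
            [(15, 30, 3, 9), (20, 22, 4, 4), (18, 36, 2, 8), (16, 17, 3, 3)]
        ):
            for frames, n, tr, tp in (
                (start_frames, n_s, tr_s, "start"),
                (end_frames, n_e, tr_e, "end"),
            ):
                cells = make_cells(
                    rng.uniform(0, 40, size=(n, 3)),
                    [True] * tr + [False] * (n - tr),
                    acinus_id=f"a{i}",
                )
                cells["timepoint"] = tp
                frames.append(cells)
        return (
            CohortTable(pd.concat(start_frames, ignore_index=True)),
            CohortTable(pd.concat(end_frames, ignore_index=True)),
        )

    def test_proliferation_rates_and_flags(self):
        start, end = self._cohorts()
        clusters = {
            "a0": [Cluster("a0", "cluster_0", ["c000"], np.zeros(3), 0.0, True)],
            "a1": [Cluster("a1", "cluster_0", ["c000"], np.zeros(3), 0.0, False)],
            "a2": [Cluster("a2", "cluster_0", ["c000"], np.zeros(3), 0.0, True)],
            "a3": [Cluster("a3", "cluster_0", ["c000"], np.zeros(3), 0.0, False)],
        }
        summary, comparison = acinus_summaries(start, end, clusters)
        a0 = summary.set_index("acinus_id").loc["a0"]
        # normal cells 12 -> 21, transduced 3 -> 9
        assert a0["proliferation_rate_normal"] == pytest.approx((21 - 12) / 12)
        assert a0["proliferation_rate_transduced"] == pytest.approx(2.0)
        assert a0["has_tumor"]
        assert set(comparison["feature"]) <= {
            "n_cells_start", "n_cells_end", "n_transduced_start",
            "n_transduced_end", "density_start", "density_end",
            "proliferation_rate_transduced", "proliferation_rate_normal",
        }
        assert comparison["p_value"].between(0, 1).all()
        assert "p_bh" in comparison.columns
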