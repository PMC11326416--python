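"""Morphometric features: tree metrics, root angles, centripetal bias,
convex hull and Sholl profiles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from morphoelec.features import MORPH_FEATURES
from morphoelec.morphology import Morphology, Node, parse_swc
from morphoelec.morphometry import (
    centripetal_bias,
    convex_hull_metrics,
    extract_morph_features,
    hull_metrics,
    root_angles,
    sholl_profile,
    tree_metrics,
)


def chain(points, radius=1.0, soma_radius=6.0):
    """Soma at points[0] with a single unbranched neurite through the rest."""
    nodes = [Node(1, 1, *points[0], soma_radius, None)]
    for i, p in enumerate(points[1:], start=2):
        nodes.append(Node(i, 3, *p, radius, i - 1))
    return Morphology(nodes)


def sample_vmf_angles(kappa, n, rng):
    """Independent polar angles from a von Mises-Fisher distribution via the
    inverse CDF of cos(theta) (test oracle)."""
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    return np.arccos(np.clip(w, -1.0, 1.0))


class TestTreeMetrics:
    def test_straight_cylinder_geometry(self):
        pts = [(0, 0, 0)] + [(10 * i, 0, 0) for i in range(1, 11)]
        out = tree_metrics(chain(pts))
        assert out["total_length"] == pytest.approx(100.0)
        assert out["total_area"] == pytest.approx(2 * math.pi * 1.0 * 100.0)
        assert out["n_primary"] == 1
        assert out["n_branch_points"] == 0
        assert out["length_normalized"] == pytest.approx(100.0)

    def test_single_bifurcation_orders(self):
        nodes = [
            Node(1, 1, 0, 0, 0, 6, None),
            Node(2, 3, 10, 0, 0, 1, 1),
            Node(3, 3, 20, 5, 0, 1, 2),
            Node(4, 3, 20, -5, 0, 1, 2),
        ]
        out = tree_metrics(Morphology(nodes))
        assert out["n_branch_points"] == 1
        assert out["n_first_order"] == 2
        assert out["n_second_order"] == 0
        assert out["branch_points_normalized"] == pytest.approx(1.0)

    def test_soma_only_tree(self):
        out = tree_metrics(parse_swc("1 1 0 0 0 6 -1\n"))
        assert out["total_length"] == 0.0
        assert out.is_missing("length_normalized")

    def test_matches_brute_force_traversal(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, _ = grow_morphology(MorphGenParams(total_length=300.0, seed=3,
                                              branch_rate=0.02))
        out = tree_metrics(m)
        # oracle: naive per-node accumulation
        length = sum(
            np.linalg.norm(np.array([n.x, n.y, n.z]) - np.array(
                [m.node(n.parent_id).x, m.node(n.parent_id).y, m.node(n.parent_id).z]))
            for n in m.nodes if n.parent_id is not None and n.type_code != 1
        )
        branch = sum(
            1 for n in m.nodes
            if n.type_code != 1 and len(m.children(n.id)) >= 2
        )
        assert out["total_length"] == pytest.approx(length)
        assert out["n_branch_points"] == branch


class TestRootAngles:
    def test_radial_neurite_scores_zero(self):
        pts = [(0, 0, 0)] + [(5 * i, 0, 0) for i in range(1, 21)]
        angles = root_angles(chain(pts))
        assert np.all(angles < 1e-9)

    def test_tangential_segment_scores_right_angle(self):
        nodes = [
            Node(1, 1, 0, 0, 0, 6, None),
            Node(2, 3, 100, 0, 0, 1, 1),
            Node(3, 3, 100, 1e-3, 0, 1, 2),
        ]
        angles = root_angles(Morphology(nodes), resample_step=1.0)
        # the tangential segment contributes an angle of ~pi/2 at its start
        assert angles.max() == pytest.approx(math.pi / 2, abs=1e-3)

    def test_matches_per_point_brute_force(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, _ = grow_morphology(MorphGenParams(total_length=150.0, seed=9, kappa=5.0))
        got = np.sort(root_angles(m, resample_step=1.0))
        soma = m.root.xyz
        expected = []
        for parent, child in m.neurite_segments():
            seg = child.xyz - parent.xyz
            length = float(np.linalg.norm(seg))
            u = seg / length
            n_pts = max(int(math.ceil(length / 1.0 - 1e-12)), 1)
            for off in np.arange(n_pts) * 1.0:
                x = parent.xyz + off * u
                to_soma = soma - x
                d = np.linalg.norm(to_soma)
                if d <= 1e-9:
                    continue
                expected.append(math.acos(np.clip(to_soma @ -u / d, -1, 1)))
        assert np.allclose(got, np.sort(expected), atol=1e-9)


class TestCentripetalBias:
    def test_vmf_sample_recovers_concentration(self, rng):
        angles = sample_vmf_angles(15.0, 2000, rng)
        assert centripetal_bias(angles) == pytest.approx(15.0, rel=0.10)

    def test_uniform_directions_give_zero_concentration(self, rng):
        angles = np.arccos(rng.uniform(-1, 1, 5000))
        assert centripetal_bias(angles) < 0.1

    def test_degenerate_all_zero_angles_clamped(self):
        assert centripetal_bias(np.zeros(100)) == 1000.0

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            centripetal_bias(np.zeros(9))

    @pytest.mark.parametrize("kappa", [2.0, 8.0, 30.0])
    def test_fisher_closed_form_matches_numerical_mle(self, kappa, rng):
        """The closed-form estimator tracks the exact maximum-likelihood
        solution of coth(k) - 1/k = rbar (the approximation itself is good
        to a few percent at moderate concentrations)."""
        angles = sample_vmf_angles(kappa, 4000, rng)
        rbar = float(np.mean(np.cos(angles)))
        mle = brentq(lambda k: 1 / np.tanh(k) - 1 / k - rbar, 1e-3, 1e4)
        assert centripetal_bias(angles) == pytest.approx(mle, rel=0.06)

    def test_monotone_in_generating_concentration(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        estimates = []
        for kappa in (1.0, 5.0, 15.0, 50.0):
            m, _ = grow_morphology(MorphGenParams(kappa=kappa, seed=21,
                                                  total_length=800.0,
                                                  max_extent=np.inf))
            estimates.append(centripetal_bias(root_angles(m)))
        assert estimates == sorted(estimates)


class TestConvexHull:
    def test_unit_cube_closed_form(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)])
        area, volume, sphericity = hull_metrics(corners)
        assert volume == pytest.approx(1.0)
        assert area == pytest.approx(6.0)
        assert sphericity == pytest.approx(math.pi ** (1 / 3) * 6 ** (2 / 3) / 6, abs=1e-6)

    def test_sphere_sampling_approaches_unit_sphericity(self, rng):
        v = rng.standard_normal((2000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        _, _, sphericity = hull_metrics(v)
        assert sphericity >= 0.99

    def test_nonspherical_hull_below_one(self, rng):
        pts = rng.standard_normal((200, 3)) * np.array([5.0, 1.0, 1.0])
        _, _, sphericity = hull_metrics(pts)
        assert sphericity < 1.0

    def test_coplanar_points_marked_missing(self):
        pts = [(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0), (5, 5, 0)]
        out = convex_hull_metrics(chain(pts))
        assert out.is_missing("hull_area")
        assert "degenerate" in out.reasons["sphericity"]


class TestShollProfile:
    def test_straight_radial_neurite(self):
        pts = [(0, 0, 0)] + [(5 * i, 0, 0) for i in range(1, 20)]  # 95 um
        radii, counts = sholl_profile(chain(pts))
        for r, c in zip(radii, counts):
            assert c == (1 if r <= 90 else 0), r

    def test_symmetric_bifurcation(self):
        nodes = [Node(1, 1, 0, 0, 0, 6, None), Node(2, 3, 25, 0, 0, 1, 1),
                 Node(3, 3, 60, 20, 0, 1, 2), Node(4, 3, 60, -20, 0, 1, 2)]
        radii, counts = sholl_profile(Morphology(nodes))
        by_r = dict(zip(radii, counts))
        assert by_r[10.0] == 1 and by_r[20.0] == 1
        assert by_r[30.0] == 2 and by_r[40.0] == 2 and by_r[50.0] == 2

    def test_soma_only_tree_all_zero(self):
        radii, counts = sholl_profile(parse_swc("1 1 0 0 0 6 -1\n"))
        assert np.all(counts == 0)

    def test_innermost_shell_counts_primaries(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, gt = grow_morphology(MorphGenParams(n_primary=5, total_length=400.0,
                                               branch_rate=0.0, kappa=80.0, seed=2))
        radii, counts = sholl_profile(m)
        assert counts[0] == gt.n_primary


class TestExtractMorphFeatures:
    def test_generated_tree_full_vector(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, gt = grow_morphology(MorphGenParams(total_length=600.0, seed=11,
                                               branch_rate=0.01))
        vec = extract_morph_features(m)
        assert set(vec.values) == set(MORPH_FEATURES)
        assert vec["total_length"] == pytest.approx(gt.total_length)
        assert vec["n_primary"] == gt.n_primary
        assert vec["n_branch_points"] == gt.n_branch_points

    def test_soma_only_everything_degenerate(self):
        vec = extract_morph_features(parse_swc("1 1 0 0 0 6 -1\n"))
        assert vec["total_length"] == 0.0
        assert vec.is_missing("centripetal_bias")
        assert vec.is_missing("hull_area")

    def test_deterministic_on_repeat(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, _ = grow_morphology(MorphGenParams(total_length=300.0, seed=4))
        assert extract_morph_features(m).values == extract_morph_features(m).values


class TestGeometricInvariance:
    @staticmethod
    def _transform(m, rotation, translation, scale=1.0):
        nodes = []
        for n in m.nodes:
            p = scale * (rotation @ np.array([n.x, n.y, n.z])) + translation
            nodes.append(Node(n.id, n.type_code, *p, n.radius * scale, n.parent_id))
        return Morphology(nodes)

    def test_rigid_motion_leaves_features_unchanged(self):
        from scipy.spatial.transform import Rotation
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, _ = grow_morphology(MorphGenParams(total_length=400.0, seed=6,
                                              branch_rate=0.01))
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        m2 = self._transform(m, rot, np.array([12.0, -7.0, 30.0]))
        v1, v2 = extract_morph_features(m), extract_morph_features(m2)
        for name in MORPH_FEATURES:
            assert v2[name] == pytest.approx(v1[name], rel=1e-6, abs=1e-9), name

    def test_uniform_scaling_laws(self):
        from morphoelec.synth_morph import MorphGenParams, grow_morphology

        m, _ = grow_morphology(MorphGenParams(total_length=400.0, seed=8,
                                              branch_rate=0.01))
        s = 2.5
        m2 = self._transform(m, np.eye(3), np.zeros(3), scale=s)
        # the resampling resolution scales with the object
        v1 = extract_morph_features(m, resample_step=1.0)
        v2 = extract_morph_features(m2, resample_step=s)
        assert v2["total_length"] == pytest.approx(s * v1["total_length"], rel=1e-9)
        assert v2["total_area"] == pytest.approx(s**2 * v1["total_area"], rel=1e-9)
        assert v2["hull_volume"] == pytest.approx(s**3 * v1["hull_volume"], rel=1e-9)
        assert v2["sphericity"] == pytest.approx(v1["sphericity"], rel=1e-9)
        assert v2["n_branch_points"] == v1["n_branch_points"]
        assert v2["centripetal_bias"] == pytest.approx(v1["centripetal_bias"], rel=1e-6)
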