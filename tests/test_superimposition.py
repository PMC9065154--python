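import numpy as np
import pytest

import clawmorph as cm
from clawmorph.superimposition import (
    GeneralizedProcrustes,
    center_and_scale,
    optimal_rotation,
    procrustes_distance,
)

from .oracles import (
    grid_procrustes_distance,
    plain_gpa_reference,
    two_shape_procrustes_residual,
)


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCenterAndScale:
    def test_two_point_example(self):
        out = center_and_scale(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(out, [[-1 / np.sqrt(2), 0], [1 / np.sqrt(2), 0]])

    def test_idempotent(self, rng):
        shape = rng.normal(size=(9, 2))
        once = center_and_scale(shape)
        assert np.allclose(center_and_scale(once), once, atol=1e-12)
        assert abs(np.linalg.norm(once)) - 1 < 1e-12
        assert np.allclose(once.mean(axis=0), 0, atol=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            center_and_scale(np.ones((5, 2)))


class TestOptimalRotation:
    def test_exact_recovery_of_known_rotation(self, rng):
        ref = center_and_scale(rng.normal(size=(7, 2)))
        rotated = ref @ _rot(np.radians(30)).T
        back = optimal_rotation(rotated, ref)
        assert np.linalg.norm(back - ref) < 1e-10

    def test_identity_when_reference_is_self(self, rng):
        shape = center_and_scale(rng.normal(size=(5, 2)))
        assert np.allclose(optimal_rotation(shape, shape), shape, atol=1e-12)

    def test_matches_complex_closed_form_oracle(self, rng):
        for _ in range(25):
            a = center_and_scale(rng.normal(size=(8, 2)))
            b = center_and_scale(rng.normal(size=(8, 2)))
            resid = np.linalg.norm(optimal_rotation(a, b) - b)
            assert resid == pytest.approx(
                two_shape_procrustes_residual(a, b), abs=1e-10
            )

    def test_k_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            optimal_rotation(np.zeros((3, 2)), np.zeros((4, 2)))


class TestProcrustesDistance:
    def test_zero_on_self_and_similarity_copies(self, rng):
        shape = rng.normal(size=(6, 2))
        assert procrustes_distance(shape, shape) == pytest.approx(0, abs=1e-12)
        copy = 2.5 * shape @ _rot(1.2).T + [3, -4]
        assert procrustes_distance(shape, copy) == pytest.approx(0, abs=1e-10)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 10, 2))
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), abs=1e-12
            )

    def test_triangle_example_matches_grid_oracle(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        b = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        assert procrustes_distance(a, b) == pytest.approx(
            grid_procrustes_distance(a, b), abs=1e-8
        )


class TestGPA:
    def test_similarity_copies_collapse(self, rng):
        base = rng.normal(size=(16, 2))
        configs = []
        for i in range(6):
            theta = rng.uniform(0, 2 * np.pi)
            scale = rng.uniform(0.2, 5)
            shift = rng.normal(0, 10, 2)
            configs.append(
                cm.LandmarkConfiguration(
                    f"c{i}", scale * base @ _rot(theta).T + shift
                )
            )
        res = cm.gpa(cm.LandmarkDataset(configs))
        n = len(configs)
        for i in range(n):
            for j in range(i):
                d = procrustes_distance(res.aligned[i], res.aligned[j])
                assert d < 1e-10
        assert procrustes_distance(res.consensus, base) < 1e-10

    def test_two_shapes_equidistant_from_consensus(self, rng):
        a = rng.normal(size=(8, 2))
        b = rng.normal(size=(8, 2))
        ds = cm.LandmarkDataset(
            [cm.LandmarkConfiguration("a", a), cm.LandmarkConfiguration("b", b)]
        )
        res = cm.gpa(ds, project_to_tangent=False)
        da = np.linalg.norm(res.aligned[0] - res.consensus)
        db = np.linalg.norm(res.aligned[1] - res.consensus)
        assert da == pytest.approx(db, rel=1e-6)

    def test_similarity_invariance_of_whole_dataset(self, claw_data):
        dataset, _, _ = claw_data
        res1 = cm.gpa(dataset, sliders=cm.claw_sliders())
        transformed = cm.LandmarkDataset(
            [
                c.with_coords(3.7 * c.coords @ _rot(1.1).T + [5.0, -2.0])
                for c in dataset
            ]
        )
        res2 = cm.gpa(transformed, sliders=cm.claw_sliders())
        assert np.abs(res1.aligned - res2.aligned).max() < 1e-8

    def test_objective_monotone_without_sliding(self, claw_data):
        dataset, _, _ = claw_data
        res = cm.gpa(dataset)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-10).all()

    def test_sliding_never_moves_fixed_landmarks(self, gpa_result):
        sliders = cm.claw_sliders()
        fixed = sorted(set(range(16)) - set(sliders.slider_indices))
        assert np.all(gpa_result.sliding_displacement[:, fixed] == 0)

    def test_result_invariants(self, claw_data):
        dataset, _, _ = claw_data
        res = cm.gpa(dataset, sliders=cm.claw_sliders(),
                     project_to_tangent=False)
        for shape in res.aligned:
            assert np.linalg.norm(shape.mean(axis=0)) < 1e-8
            assert abs(np.linalg.norm(shape) - 1) < 1e-8
        assert np.abs(res.aligned.mean(axis=0) - res.consensus).max() < 1e-6
        assert res.final_delta < 1e-8

    def test_sliding_reduces_objective_on_reparameterized_curve(self):
        # same quarter-circle arc, semi-landmarks unevenly re-spaced per
        # specimen: sliding should absorb the spacing differences
        rng = np.random.default_rng(7)
        configs = []
        for i in range(8):
            u = np.sort(rng.uniform(0.05, 0.95, size=6))
            t = np.concatenate([[0.0], u, [1.0]])
            ang = t * np.pi / 2
            coords = np.column_stack([np.cos(ang), np.sin(ang)])
            configs.append(cm.LandmarkConfiguration(f"arc{i}", coords))
        ds = cm.LandmarkDataset(configs)
        rows = tuple((j - 1, j, j + 1) for j in range(1, 7))
        sliders = cm.SliderTable(rows)
        res_slide = cm.gpa(ds, sliders=sliders, mode="procd")
        res_plain = cm.gpa(ds)
        q_slide = np.mean(
            [
                procrustes_distance(s, res_slide.consensus)
                for s in res_slide.aligned
            ]
        )
        q_plain = np.mean(
            [
                procrustes_distance(s, res_plain.consensus)
                for s in res_plain.aligned
            ]
        )
        assert q_slide < q_plain

    def test_matches_independent_plain_gpa_to_1e6(self, rng):
        shapes = rng.normal(size=(6, 10, 2)) + 5 * np.cos(
            np.linspace(0, np.pi, 10)
        )[None, :, None]
        est = GeneralizedProcrustes(project_to_tangent=False)
        est.fit(shapes)
        ref = plain_gpa_reference(shapes)
        # orientations are gauge; compare via pairwise Procrustes distances
        n = len(shapes)
        for i in range(n):
            for j in range(i):
                d_pkg = np.linalg.norm(est.result_.aligned[i]
                                       - est.result_.aligned[j])
                d_ref = np.linalg.norm(ref[i] - ref[j])
                assert d_pkg == pytest.approx(d_ref, abs=1e-6)

    def test_bending_energy_mode_converges(self, claw_data):
        dataset, _, _ = claw_data
        res = cm.gpa(dataset, sliders=cm.claw_sliders(),
                     mode="bending_energy")
        assert res.final_delta < 1e-8
        assert res.iterations < 100

    def test_transform_aligns_new_shapes(self, claw_data):
        dataset, _, _ = claw_data
        est = GeneralizedProcrustes(project_to_tangent=False).fit(dataset)
        new = est.transform(dataset.coords_array()[:3] * 4.0 + 10.0)
        assert np.abs(new - est.result_.aligned[:3]).max() < 1e-6

    def test_requires_two_configurations(self, rng):
        with pytest.raises(ValueError, match="at least two"):
            cm.gpa(np.zeros((1, 5, 2)))
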