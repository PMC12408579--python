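"""Counting-loss correctness: analytic values, weighting, gradients."""

import numpy as np
import pytest

from tcdnet._tensor import Tensor
from tcdnet.annotations import (AnnotationSet, BoundingBox, BoundaryMatrix,
                                CenterMatrix, build_boundary_matrix,
                                build_center_matrix)
from tcdnet.loss import (boundary_loss, false_positive_loss,
                         false_positive_region_mask, localization_loss, oc_loss)
from tcdnet.model import ProbabilityMap

LOG2 = float(np.log(2.0))


def pmap_from(values):
    return ProbabilityMap.from_values(np.asarray(values, dtype=np.float64))


def centers_at(shape, coords):
    m = np.zeros(shape, np.uint8)
    for r, c in coords:
        m[r, c] = 1
    return CenterMatrix(m)


def boundary_at(shape, coords):
    m = np.zeros(shape, np.uint8)
    for r, c in coords:
        m[r, c] = 1
    return BoundaryMatrix(m)


class TestLocalization:
    def test_perfect_prediction_is_zero(self):
        p = pmap_from(np.full((8, 8), 1 - 1e-9))
        loss, _ = localization_loss(p, centers_at((8, 8), [(2, 2), (5, 5)]))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_single_center(self):
        p = pmap_from(np.full((8, 8), 0.5))
        loss, _ = localization_loss(p, centers_at((8, 8), [(3, 3)]))
        assert loss == pytest.approx(LOG2, rel=1e-5)

    def test_lambda_scales_with_count(self):
        # two centers at P=0.5: lambda_L=2, loss = 2 * (log2 + log2)
        p = pmap_from(np.full((8, 8), 0.5))
        loss, _ = localization_loss(p, centers_at((8, 8), [(1, 1), (6, 6)]))
        assert loss == pytest.approx(4 * LOG2, rel=1e-5)

    def test_no_centers_gives_zero(self):
        p = pmap_from(np.full((4, 4), 0.9))
        loss, term = localization_loss(p, centers_at((4, 4), []))
        assert loss == 0.0 and term is None


class TestBoundary:
    def test_zero_probability_boundary_is_zero(self):
        p = pmap_from(np.full((8, 8), 1e-9))
        loss, _ = boundary_loss(p, boundary_at((8, 8), [(0, 0), (1, 1)]), 3)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_single_object_unweighted(self):
        # lambda_B = n-1 = 0: no constraint regardless of P
        p = pmap_from(np.full((8, 8), 0.99))
        loss, _ = boundary_loss(p, boundary_at((8, 8), [(2, 2)]), 1)
        assert loss == 0.0

    def test_two_objects_one_pixel(self):
        p = pmap_from(np.full((8, 8), 0.5))
        loss, _ = boundary_loss(p, boundary_at((8, 8), [(4, 4)]), 2)
        assert loss == pytest.approx(LOG2, rel=1e-5)

    def test_inverse_count_mode(self):
        p = pmap_from(np.full((8, 8), 0.5))
        loss, _ = boundary_loss(p, boundary_at((8, 8), [(4, 4)]), 4,
                                lambda_mode="inverse_count")
        assert loss == pytest.approx(LOG2 / 4, rel=1e-5)


class TestFalsePositive:
    def test_components_with_centers_are_free(self):
        v = np.zeros((8, 8))
        v[2:4, 2:4] = 0.9
        loss, _ = false_positive_loss(pmap_from(v), centers_at((8, 8), [(2, 2)]))
        assert loss == 0.0

    def test_empty_prediction_is_zero(self):
        loss, _ = false_positive_loss(pmap_from(np.full((8, 8), 0.1)),
                                      centers_at((8, 8), [(2, 2)]))
        assert loss == 0.0

    def test_center_free_component_penalized(self):
        # two 2-pixel components at P=0.8, only one holds a center
        v = np.full((8, 8), 0.1)
        v[1, 1:3] = 0.8
        v[6, 5:7] = 0.8
        loss, _ = false_positive_loss(pmap_from(v), centers_at((8, 8), [(1, 1)]))
        assert loss == pytest.approx(-2 * np.log(0.2), rel=1e-4)

    def test_region_mask_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.random((16, 16))
            centers = centers_at((16, 16), [(int(rng.integers(16)), int(rng.integers(16)))
                                            for _ in range(3)])
            mask = false_positive_region_mask(v, centers, 0.5, 4)
            # brute-force flood fill
            binary = v >= 0.5
            seen = np.zeros_like(binary)
            expected = np.zeros_like(binary)
            for sr in range(16):
                for sc in range(16):
                    if binary[sr, sc] and not seen[sr, sc]:
                        stack, comp = [(sr, sc)], []
                        seen[sr, sc] = True
                        while stack:
                            r, c = stack.pop()
                            comp.append((r, c))
                            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                rr, cc = r + dr, c + dc
                                if 0 <= rr < 16 and 0 <= cc < 16 and \
                                        binary[rr, cc] and not seen[rr, cc]:
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                        if not any(centers.values[r, c] for r, c in comp):
                            for r, c in comp:
                                expected[r, c] = True
            np.testing.assert_array_equal(mask, expected)


class TestOCLoss:
    def make_scene(self):
        ann = AnnotationSet("s", 32, 32, [BoundingBox(4, 4, 10, 10),
                                          BoundingBox(20, 18, 26, 25)])
        return ann, build_center_matrix(ann), build_boundary_matrix(ann)

    def test_perfect_prediction_total_zero(self):
        ann, t_l, t_b = self.make_scene()
        v = np.full((32, 32), 1e-9)
        for b in ann.boxes:
            r, c = b.center_pixel()
            v[r - 1:r + 2, c - 1:c + 2] = 1 - 1e-9   # small blob inside each box
        br = oc_loss(pmap_from(v), t_l, t_b)
        assert br.total == pytest.approx(0.0, abs=1e-5)

    def test_total_is_sum_of_terms(self):
        _, t_l, t_b = self.make_scene()
        v = np.random.default_rng(1).random((32, 32))
        p = pmap_from(v)
        br = oc_loss(p, t_l, t_b)
        assert br.total == pytest.approx(
            localization_loss(p, t_l)[0]
            + boundary_loss(p, t_b, t_l.n_centers)[0]
            + false_positive_loss(p, t_l)[0], rel=1e-6)

    def test_terms_nonnegative_property(self):
        rng = np.random.default_rng(2)
        _, t_l, t_b = self.make_scene()
        for _ in range(10):
            br = oc_loss(pmap_from(rng.random((32, 32))), t_l, t_b)
            assert br.localization >= 0 and br.boundary >= 0 and br.false_positive >= 0

    def test_gradient_matches_finite_differences(self):
        _, t_l, t_b = self.make_scene()
        rng = np.random.default_rng(3)
        logits = rng.normal(0, 1, (32, 32)).astype(np.float32)
        t = Tensor(logits.copy(), requires_grad=True)
        p = ProbabilityMap(t.data, logits_tensor=t)
        br = oc_loss(p, t_l, t_b)
        br.total_tensor.backward()
        # analytic check at a center pixel: dL_L/dz = lambda_L * (P - 1)
        r, c = np.argwhere(t_l.values)[0]
        pr = 1 / (1 + np.exp(-float(logits[r, c])))
        lam = t_l.n_centers
        assert t.grad[r, c] == pytest.approx(lam * (pr - 1), rel=1e-3)
        # finite differences on a few pixels (center, boundary, background)
        check = [tuple(np.argwhere(t_l.values)[0]), tuple(np.argwhere(t_b.values)[0]), (0, 0)]
        h = 1e-3
        for (rr, cc) in check:
            def f(delta):
                z = logits.copy()
                z[rr, cc] += delta
                zt = Tensor(z)
                return oc_loss(ProbabilityMap(z, logits_tensor=zt), t_l, t_b).total
            num = (f(h) - f(-h)) / (2 * h)
            assert t.grad[rr, cc] == pytest.approx(num, rel=2e-2, abs=1e-4)

    def test_term_selection_for_ablation(self):
        _, t_l, t_b = self.make_scene()
        p = pmap_from(np.random.default_rng(4).random((32, 32)))
        br = oc_loss(p, t_l, t_b, terms=("localization",))
        assert br.boundary == 0.0 and br.false_positive == 0.0
        assert br.localization > 0
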