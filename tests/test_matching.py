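"""Crossover geometry, wedge admissibility, constrained matching, cutting."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from headrice import concavity, matching, synthetic

from conftest import STRUCT8, TEMPLATE, chain_scene


def reflex_corner_mask(size=40):
    """L-shaped mask whose traced boundary passes through the reflex
    (concave) corner pixel at (20, 20): the background notch covers
    rows < 20, cols < 21."""
    m = np.ones((size, size), dtype=bool)
    m[:20, :21] = False
    return m


class TestCrossoverPoints:
    def test_reflex_corner_crossovers_on_straight_edges(self):
        m = reflex_corner_mask()
        b = concavity.trace_boundary(m)
        apex = (20, 20)
        idx = int(np.flatnonzero((b.points == apex).all(axis=1))[0])
        M, N = matching.crossover_points(b, idx, 9)
        for p in (M, N):
            assert max(abs(p[0] - apex[0]), abs(p[1] - apex[1])) == 4
        # one crossover per incident straight edge: one on the horizontal
        # edge (apex row), the other on the vertical edge (next column)
        assert apex[0] in (M[0], N[0])
        assert apex[1] + 1 in (M[1], N[1])
        assert M != N

    def test_symmetric_neck_is_balanced(self, two_grain):
        _, mask, boundary, profile = two_grain
        for t in profile.concave_indices:
            M, N = matching.crossover_points(boundary, int(t), TEMPLATE)
            a = boundary.points[t]
            dm = np.hypot(M[0] - a[0], M[1] - a[1])
            dn = np.hypot(N[0] - a[0], N[1] - a[1])
            assert M != N
            assert abs(dm - dn) <= 3.0

    def test_tiny_boundary_raises(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3:5, 3:5] = True
        b = concavity.trace_boundary(m)
        with pytest.raises(ValueError):
            matching.crossover_points(b, 0, 9)


def corner_point(apex=(20, 20)):
    """ConcavePoint at a reflex 90-degree corner: M west of apex on the
    horizontal edge, N north of it on the vertical edge."""
    return matching.ConcavePoint(
        position=apex,
        boundary_index=0,
        component_label=1,
        crossover_m=(apex[0], apex[1] - 4),
        crossover_n=(apex[0] - 4, apex[1]),
        interior_direction=(1.0, 1.0),
    )


class TestAdmissibleRegion:
    def test_ray_opposite_m_is_admissible(self):
        cp = corner_point()
        pred = matching.admissible_region(cp)
        assert pred((20, 26))  # opposite AM (east)
        assert pred((26, 20))  # opposite AN (south)
        assert pred((26, 26))  # inside the wedge

    def test_crossover_itself_not_admissible(self):
        cp = corner_point()
        pred = matching.admissible_region(cp)
        assert not pred(cp.crossover_m)
        assert not pred(cp.crossover_n)
        assert not pred((14, 14))  # into the background notch

    def test_neck_partner_admissible_convex_points_not(self, two_grain):
        _, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        assert len(cps) == 2
        a, b = cps
        assert matching.admissible_region(a)(b.position)
        assert matching.admissible_region(b)(a.position)
        # the wedge points across the neck, so every convex boundary point
        # on the basic point's own side is rejected
        n = len(boundary)
        for cp in (a, b):
            pred = matching.admissible_region(cp)
            for dt in range(-n // 4, n // 4):
                if abs(dt) < 25:  # skip the neck vicinity itself
                    continue
                t = (cp.boundary_index + dt) % n
                assert not pred(tuple(boundary.points[t]))

    def test_degenerate_wedge_uses_interior_halfplane(self):
        cp = matching.ConcavePoint(
            position=(10, 10),
            boundary_index=0,
            component_label=1,
            crossover_m=(10, 6),
            crossover_n=(10, 14),
            interior_direction=(1.0, 0.0),
        )
        pred = matching.admissible_region(cp)
        assert pred((15, 10))
        assert not pred((5, 10))


class TestMatching:
    def test_two_points_one_pair(self, two_grain):
        _, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        pairs = matching.match_concave_points(cps)
        assert len(pairs) == 1
        assert pairs[0].cut_length > 0

    def test_empty_input(self):
        assert matching.match_concave_points([]) == []

    def test_chain_pairs_cross_the_necks(self, three_chain):
        scene, mask, boundary, profile = three_chain
        cps = matching.build_concave_points(mask, boundary, profile)
        assert len(cps) == 4
        pairs = matching.match_concave_points(cps)
        assert len(pairs) == 2
        # each pair must straddle one contact: its midpoint lies in the
        # overlap neighborhood of one consecutive grain pair
        shape = scene.truth_labels.shape
        masks = [synthetic.make_grain_mask(s, shape) for s in scene.truth_specs]
        necks = [a & b for a, b in zip(masks, masks[1:])]
        hit = set()
        for pair in pairs:
            mid = (
                (pair.bp.position[0] + pair.mp.position[0]) / 2,
                (pair.bp.position[1] + pair.mp.position[1]) / 2,
            )
            dists = []
            for neck in necks:
                rs, cs = np.nonzero(neck)
                dists.append(np.hypot(rs - mid[0], cs - mid[1]).min())
            hit.add(int(np.argmin(dists)))
            assert min(dists) <= 6.0
        assert hit == {0, 1}

    def test_pairs_never_span_components(self):
        s1 = chain_scene(2, seed=90)
        s2 = chain_scene(2, seed=91)
        # paste both clusters into one image, far apart
        h = max(s1.image.shape[0], s2.image.shape[0])
        w = s1.image.shape[1] + s2.image.shape[1] + 60
        mask = np.zeros((h, w), dtype=bool)
        mask[: s1.image.shape[0], : s1.image.shape[1]] = s1.truth_labels > 0
        mask[: s2.image.shape[0], s1.image.shape[1] + 60 :] = s2.truth_labels > 0
        labels, n = ndi.label(mask, structure=STRUCT8)
        assert n == 2
        points = []
        for lab in range(1, 3):
            b = concavity.trace_boundary(labels, lab)
            prof = concavity.ecmp_profile(mask, b, TEMPLATE)
            concavity.compute_lambda(prof, 3.0)
            concavity.find_concave_points(prof)
            points.extend(matching.build_concave_points(mask, b, prof))
        pairs = matching.match_concave_points(points)
        assert len(pairs) == 2
        for p in pairs:
            assert p.bp.component_label == p.mp.component_label

    def test_mirrored_scene_gives_mirrored_pairs(self, two_grain):
        _, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        pairs = matching.match_concave_points(cps)

        flipped = np.fliplr(mask)
        fb = concavity.trace_boundary(flipped)
        fprof = concavity.ecmp_profile(flipped, fb, TEMPLATE)
        concavity.compute_lambda(fprof, 3.0)
        concavity.find_concave_points(fprof)
        fcps = matching.build_concave_points(flipped, fb, fprof)
        fpairs = matching.match_concave_points(fcps)
        assert len(fpairs) == len(pairs) == 1
        w = mask.shape[1]
        orig = {
            frozenset(
                [pairs[0].bp.position, pairs[0].mp.position]
            )
        }
        mirrored = {
            frozenset(
                [
                    (fpairs[0].bp.position[0], w - 1 - fpairs[0].bp.position[1]),
                    (fpairs[0].mp.position[0], w - 1 - fpairs[0].mp.position[1]),
                ]
            )
        }
        # mirrored pair endpoints agree with the original up to rasterization
        (o,) = orig
        (m,) = mirrored
        for p in o:
            assert min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in m) <= 2.0


class TestSeparate:
    def test_single_convex_grain_untouched(self):
        s = synthetic.GrainSpec(
            center=(50, 50), orientation=20.0, semi_major=30, semi_minor=12
        )
        mask = synthetic.make_grain_mask(s, (100, 100))
        labels = matching.separate(mask, [])
        assert labels.max() == 1
        assert np.array_equal(labels > 0, mask)

    def test_two_grain_cluster_splits_into_truth_areas(self, two_grain):
        scene, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        pairs = matching.match_concave_points(cps)
        labels = matching.separate(mask, pairs)
        assert labels.max() == 2
        truth_areas = sorted(scene.truth_areas())
        got_areas = sorted(np.bincount(labels.ravel())[1:])
        for got, want in zip(got_areas, truth_areas):
            assert got == pytest.approx(want, rel=0.10)

    def test_pixel_conservation(self, two_grain):
        _, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        pairs = matching.match_concave_points(cps)
        labels = matching.separate(mask, pairs)
        cut_px = mask.sum() - (labels > 0).sum()
        assert (labels > 0).sum() == mask.sum() - cut_px
        assert 0 < cut_px <= 3 * pairs[0].cut_length + 3

    def test_never_creates_foreground(self, two_grain):
        _, mask, boundary, profile = two_grain
        cps = matching.build_concave_points(mask, boundary, profile)
        pairs = matching.match_concave_points(cps)
        labels = matching.separate(mask, pairs)
        assert not ((labels > 0) & ~mask).any()

    def test_failed_cut_warns_and_keeps_component(self):
        # a pair whose segment does not disconnect anything: both endpoints
        # on the same edge of a solid square
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        cp = lambda pos: matching.ConcavePoint(
            position=pos,
            boundary_index=0,
            component_label=1,
            crossover_m=(pos[0], pos[1] - 2),
            crossover_n=(pos[0] - 2, pos[1]),
            interior_direction=(1.0, 1.0),
        )
        pair = matching.MatchPair(bp=cp((5, 10)), mp=cp((5, 18)))
        with pytest.warns(UserWarning, match="disconnect"):
            labels = matching.separate(m, [pair])
        assert labels.max() == 1
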