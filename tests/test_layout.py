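import math

import numpy as np
import pytest

import vennkit as vk
from vennkit import geometry as geo
from vennkit.layout import (
    CANVAS,
    _ED_RADIUS,
    SetShape,
    compose_layout,
    points_region_keys,
)
from oracles import shapely_region_of

ALL_TEMPLATES = [
    (mode, n) for mode in ("classic", "edwards") for n in range(2, 7)
]


@pytest.fixture(scope="module")
def layouts():
    return {(m, n): vk.build_layout(m, n) for m, n in ALL_TEMPLATES}


class TestShippedTemplates:
    @pytest.mark.parametrize("mode,n", ALL_TEMPLATES)
    def test_every_region_has_a_valid_anchor(self, layouts, mode, n):
        lay = layouts[(mode, n)]
        assert len(lay.anchors) == 2**n - 1
        assert vk.validate_layout(lay) == []

    @pytest.mark.parametrize("mode,n", ALL_TEMPLATES)
    def test_generation_is_deterministic(self, layouts, mode, n):
        lay1 = layouts[(mode, n)]
        lay2 = vk.build_layout(mode, n)
        assert lay1.anchors == lay2.anchors
        assert lay1.budgets == lay2.budgets
        for s1, s2 in zip(lay1.shapes, lay2.shapes):
            for r1, r2 in zip(s1.rings, s2.rings):
                assert np.array_equal(r1, r2)

    @pytest.mark.parametrize("mode", ["classic", "edwards"])
    def test_out_of_range_set_counts_rejected(self, mode):
        for n in (1, 7):
            with pytest.raises(ValueError):
                vk.build_layout(mode, n)

    @pytest.mark.parametrize("mode,n", ALL_TEMPLATES)
    def test_name_points_sit_outside_their_shape(self, layouts, mode, n):
        lay = layouts[(mode, n)]
        for shape in lay.shapes:
            assert not geo.point_in_rings(lay.name_points[shape.label], shape.rings)


class TestPointInRegion:
    def test_triple_overlap_centre_of_three_circles(self, layouts):
        lay = layouts[("classic", 3)]
        cx = np.mean([s.rings[0][:-1, 0].mean() for s in lay.shapes])
        cy = np.mean([s.rings[0][:-1, 1].mean() for s in lay.shapes])
        assert vk.point_in_region(lay, (cx, cy)) == "ABC"

    def test_far_outside_is_nowhere(self, layouts):
        for lay in layouts.values():
            assert vk.point_in_region(lay, (-1e4, -1e4)) is None

    @pytest.mark.parametrize("mode,n", [("classic", 4), ("edwards", 6)])
    def test_agrees_with_shapely_on_random_points(self, layouts, rng, mode, n):
        lay = layouts[(mode, n)]
        pts = rng.uniform(0, CANVAS, size=(10_000, 2))
        keys = points_region_keys(lay, pts)
        # spot-check a deterministic subsample against the geometry oracle
        for i in range(0, len(pts), 250):
            assert keys[i] == shapely_region_of(lay.shapes, pts[i])
        # the vectorised path must agree with the scalar one
        for i in range(0, len(pts), 500):
            assert keys[i] == vk.point_in_region(lay, tuple(pts[i]))


class TestNegativeControls:
    def test_disjoint_circles_fail_validation(self):
        shapes = [
            SetShape("A", (geo.circle_ring((150, 350), 100),)),
            SetShape("B", (geo.circle_ring((550, 350), 100),)),
        ]
        lay = compose_layout("classic", shapes)
        report = vk.validate_layout(lay)
        assert any("AB" in line for line in report)

    def test_displaced_anchor_is_reported_by_name(self, layouts):
        lay = layouts[("classic", 2)]
        broken = vk.LayoutSpec(
            mode=lay.mode,
            n=lay.n,
            width=lay.width,
            height=lay.height,
            shapes=lay.shapes,
            anchors={**lay.anchors, "AB": (1.0, 1.0)},
            budgets=lay.budgets,
            areas=lay.areas,
            name_points=lay.name_points,
        )
        report = vk.validate_layout(broken)
        assert len(report) == 1 and "AB" in report[0]


class TestEdwardsConstruction:
    def test_two_set_case_is_two_rectangles(self, layouts):
        lay = layouts[("edwards", 2)]
        assert all(len(s.rings) == 1 for s in lay.shapes)
        assert all(len(s.rings[0]) == 5 for s in lay.shapes)  # closed quads
        assert len(lay.anchors) == 3

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_band_circle_crossings(self, layouts, k):
        """Serpentine band k crosses the circle boundary 2*2**(k-3) times."""
        lay = layouts[("edwards", 6)]
        band = lay.shapes[k - 1]
        centre = (CANVAS / 2, CANVAS / 2)
        outer, inner = band.rings[0][:-1], band.rings[1][:-1]
        radii = 0.5 * (
            np.hypot(outer[:, 0] - centre[0], outer[:, 1] - centre[1])
            + np.hypot(inner[:, 0] - centre[0], inner[:, 1] - centre[1])
        )
        signs = np.sign(radii - _ED_RADIUS)
        signs = signs[signs != 0]  # samples exactly on the boundary
        crossings = int(np.sum(signs != np.roll(signs, 1)))
        assert crossings == 2 * 2 ** (k - 3)


class TestCallouts:
    def test_tiny_regions_with_wide_counts_get_callouts(self, layouts):
        lay = layouts[("classic", 6)]
        counts = {key: 123456 for key in vk.canonical_regions("ABCDEF")}
        table = vk.RegionTable(
            labels=tuple("ABCDEF"),
            names={c: c for c in "ABCDEF"},
            counts=counts,
            elements=None,
            mode="user_supplied",
        )
        plan = vk.plan_callouts(lay, table)
        assert plan  # six-digit counts cannot fit the sliver regions
        planned = {c.region for c in plan}
        small = min(lay.areas, key=lay.areas.get)
        assert small in planned

    def test_single_digit_counts_in_roomy_regions_need_none(self, layouts):
        lay = layouts[("classic", 2)]
        table = vk.RegionTable(
            labels=("A", "B"),
            names={"A": "a", "B": "b"},
            counts={"A": 1, "B": 2, "AB": 3},
            elements=None,
            mode="user_supplied",
        )
        assert vk.plan_callouts(lay, table) == []

    @pytest.mark.parametrize("mode", ["classic", "edwards"])
    def test_leader_lines_do_not_cross(self, layouts, mode):
        lay = layouts[(mode, 6)]
        counts = {key: 987654 for key in vk.canonical_regions("ABCDEF")}
        table = vk.RegionTable(
            labels=tuple("ABCDEF"),
            names={c: c for c in "ABCDEF"},
            counts=counts,
            elements=None,
            mode="user_supplied",
        )
        plan = vk.plan_callouts(lay, table)
        segments = [(c.line[0], c.line[-1]) for c in plan]
        for i in range(len(segments)):
            for j in range(i + 1, len(segments)):
                assert not geo.segments_intersect(
                    *segments[i], *segments[j]
                ), (plan[i].region, plan[j].region)
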