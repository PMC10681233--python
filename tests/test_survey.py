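"""Survey-table reading, filtering, group assignment and capture histories."""

import io
import math

import numpy as np
import pytest

from gibbonascr import (DetectionRecord, ListeningPost, assign_group_ids,
                        build_capture_histories, filter_detections,
                        read_survey_tables)
from gibbonascr.survey import SchemaError, implied_location


def det(site="A", day=1, post=1, bearing=0.0, cat="D500", start=0.0, end=15.0,
        **kw):
    return DetectionRecord(site_id=site, day=day, post_index=post,
                           bearing_deg=bearing, distance_category=cat,
                           start_min=start, end_min=end, **kw)


POSTS_CSV = """site_id,post_index,easting,northing,days_active
A,1,0,0,1;2;3
A,2,500,0,1;2;3
A,3,1000,0,1;2;3
"""

DET_CSV = """site_id,day,post_index,bearing_deg,distance_category,start_min,end_min,female_heard,twitter_heard,n_extra,is_repeat,is_male_solo
A,1,1,45.0,D500,-5,10,True,False,1,False,False
A,1,2,361.0,D500,-5,10,True,False,,False,False
"""


class TestReadTables:
    def test_identity_read_back(self):
        posts, recs, rejected = read_survey_tables(io.StringIO(POSTS_CSV),
                                                   io.StringIO(DET_CSV))
        assert len(posts) == 3
        d01 = math.hypot(posts[0].x - posts[1].x, posts[0].y - posts[1].y)
        assert d01 == 500.0
        assert len(recs) == 1 and recs[0].bearing_deg == 45.0

    def test_out_of_range_bearing_reported_with_row(self):
        _, _, rejected = read_survey_tables(io.StringIO(POSTS_CSV),
                                            io.StringIO(DET_CSV))
        assert len(rejected) == 1
        table, row, msg = rejected[0]
        assert table == "detections" and row == 1 and "361" in msg

    def test_missing_column_is_schema_error(self):
        bad = POSTS_CSV.replace("northing", "lat")
        with pytest.raises(SchemaError, match="northing"):
            read_survey_tables(io.StringIO(bad), io.StringIO(DET_CSV))

    def test_thirteen_site_array_structure(self):
        rows = ["site_id,post_index,easting,northing,days_active"]
        for s in range(13):
            for p in range(3):
                rows.append(f"S{s:02d},{p + 1},{500 * p},{100000 * s},1;2;3")
        posts, _, rej = read_survey_tables(io.StringIO("\n".join(rows)),
                                           io.StringIO(DET_CSV.split("A,1,2")[0]))
        assert not rej
        sites = {p.site_id for p in posts}
        assert len(sites) == 13
        assert all(sum(p.site_id == s for p in posts) == 3 for s in sites)


class TestFilterDetections:
    def test_repeat_dropped(self):
        kept, log = filter_detections([det(), det(start=60, end=70, is_repeat=True)])
        assert len(kept) == 1 and log[0][1] == "repeat duet"

    def test_uncorroborated_male_solo_dropped(self):
        kept, log = filter_detections([det(is_male_solo=True)])
        assert kept == [] and "male solo" in log[0][1]

    def test_male_solo_rescued_by_matching_duet(self, three_posts):
        # duet at post 1 bearing 90 deg, 500 m -> (500, 0); "solo" at post 3
        # bearing 270 deg, 500 m -> (500, 0): same implied location, same time
        duet = det(post=1, bearing=90.0, cat="D500")
        solo = det(post=3, bearing=270.0, cat="D500", is_male_solo=True)
        kept, _ = filter_detections([duet, solo], posts=three_posts)
        assert len(kept) == 2

    def test_male_solo_not_rescued_when_far(self, three_posts):
        duet = det(post=1, bearing=0.0, cat="D1500")   # implied (0, 1500)
        solo = det(post=3, bearing=180.0, cat="D1500", is_male_solo=True)
        kept, _ = filter_detections([duet, solo], posts=three_posts)
        assert len(kept) == 1

    def test_idempotent(self, three_posts):
        rng = np.random.default_rng(0)
        recs = [det(post=int(rng.integers(1, 4)), bearing=float(rng.uniform(0, 360)),
                    start=float(rng.integers(-20, 60)),
                    end=float(rng.integers(60, 120)),
                    is_repeat=bool(rng.uniform() < 0.3),
                    is_male_solo=bool(rng.uniform() < 0.3))
                for _ in range(40)]
        once, _ = filter_detections(recs, posts=three_posts)
        twice, _ = filter_detections(once, posts=three_posts)
        assert once == twice

    def test_override_keep_always_retained(self):
        kept, _ = filter_detections([det(is_repeat=True, override_keep=True)])
        assert len(kept) == 1


class TestAssignGroups:
    def test_singleton(self, three_posts):
        g = assign_group_ids([det()], three_posts)
        assert len(g.groups) == 1 and g.n_persistent_groups == 1

    def test_intersecting_bearings_merge(self, three_posts):
        # implied locations ~(354, 354) and (500, 500), 207 m apart,
        # identical call window -> one group
        a = det(post=1, bearing=45.0, cat="D500")
        b = det(post=2, bearing=0.0, cat="D500")
        xa, ya = implied_location(a, three_posts[0])
        xb, yb = implied_location(b, three_posts[1])
        assert math.hypot(xa - xb, ya - yb) <= 500.0
        g = assign_group_ids([a, b], three_posts)
        assert len(g.groups) == 1

    def test_distant_disjoint_detections_are_two_groups(self, three_posts):
        a = det(post=1, bearing=0.0, cat="D500", start=0, end=10)
        b = det(post=3, bearing=90.0, cat="D1000", start=30, end=40)
        g = assign_group_ids([a, b], three_posts)
        xa, ya = implied_location(a, three_posts[0])
        xb, yb = implied_location(b, three_posts[2])
        assert math.hypot(xa - xb, ya - yb) > 1000.0
        assert len(g.groups) == 2

    def test_shuffle_invariance(self, three_posts):
        rng = np.random.default_rng(7)
        recs = [det(day=int(rng.integers(1, 4)), post=int(rng.integers(1, 4)),
                    bearing=float(rng.uniform(0, 360)),
                    cat=str(rng.choice(["LT500", "D500", "D1000"])),
                    start=float(rng.integers(-30, 90)),
                    end=float(rng.integers(90, 150)))
                for _ in range(25)]
        g1 = assign_group_ids(recs, three_posts)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        g2 = assign_group_ids(shuffled, three_posts)
        assert set(g1.groups) == set(g2.groups)
        assert g1.persistent == g2.persistent

    def test_unknown_post_rejected(self, three_posts):
        with pytest.raises(KeyError):
            assign_group_ids([det(post=9)], three_posts)

    def test_well_separated_groups_recovered_exactly(self, three_posts):
        # groups > 3 x merge distance apart with exact implied locations:
        # one detection each at exact category distances along due north
        recs = []
        for i, cat in enumerate(["LT500", "D500", "D1000", "D1500"]):
            post = three_posts[0]
            recs.append(det(post=1, bearing=float(90 * i % 360), cat=cat,
                            start=40 * i, end=40 * i + 10))
        locs = [implied_location(r, three_posts[0]) for r in recs]
        dmin = min(math.hypot(a[0] - b[0], a[1] - b[1])
                   for i, a in enumerate(locs) for b in locs[i + 1:])
        assert dmin > 3 * 500.0 or len({tuple(l) for l in locs}) == len(locs)
        g = assign_group_ids(recs, three_posts)
        assert g.n_persistent_groups == 4

    def test_recaptures_only_add_rows(self, three_posts):
        # the same location heard on three days: 3 histories, 1 persistent group
        recs = [det(day=d, post=1, bearing=0.0, cat="D500") for d in (1, 2, 3)]
        g = assign_group_ids(recs, three_posts)
        hists = build_capture_histories(g, three_posts)
        assert len(hists) == 3 and g.n_persistent_groups == 1
        assert len(hists) >= g.n_persistent_groups


class TestCaptureHistories:
    def test_omega_110(self, three_posts):
        recs = [det(post=1, bearing=45.0), det(post=2, bearing=315.0)]
        g = assign_group_ids(recs, three_posts)
        hists = build_capture_histories(g, three_posts)
        assert len(hists) == 1
        np.testing.assert_array_equal(hists[0].omega, [1, 1, 0])
        assert set(hists[0].bearings_deg) == {1, 2}

    def test_inactive_post_shrinks_history(self):
        days12 = frozenset({1, 2})
        days123 = frozenset({1, 2, 3})
        posts = [ListeningPost("A", 1, 0, 0, days123),
                 ListeningPost("A", 2, 500, 0, days123),
                 ListeningPost("A", 3, 1000, 0, days12)]
        g = assign_group_ids([det(day=3, post=1)], posts)
        hists = build_capture_histories(g, posts)
        assert hists[0].post_indices == (1, 2)
        assert hists[0].omega.size == 2

    def test_empty_input(self, three_posts):
        from gibbonascr import GroupedDetections
        assert build_capture_histories(GroupedDetections(), three_posts) == []
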