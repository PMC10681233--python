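"""Reading, validation and structuring of listening-post survey tables.

The raw data of an auditory survey are (i) a table of listening posts
(three per site, 500 m apart, surveyed on up to three days) and (ii) a
table of detections: one row per duet heard from one post on one day,
with a compass bearing, a coarse distance category, call start/end times
in minutes relative to sunrise, and duet features that help tell groups
apart.

This module filters the raw detections (dropping same-day repeat duets
and uncorroborated male solo calls), resolves detections into groups
(same-day merging by implied location and call-time overlap; cross-day
identity by centroid proximity) and builds the per-site-day binary
capture histories that the SCR likelihood consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ListeningPost",
    "DetectionRecord",
    "GroupedDetections",
    "CaptureHistory",
    "DISTANCE_CATEGORIES",
    "REPRESENTATIVE_DISTANCE_M",
    "read_survey_tables",
    "posts_to_frame",
    "detections_to_frame",
    "filter_detections",
    "assign_group_ids",
    "build_capture_histories",
    "implied_location",
]

#: Four-level distance scale used by observers (upper labels are the
#: spoken "500 m", "1000 m", "1500 m" categories).
DISTANCE_CATEGORIES = ("LT500", "D500", "D1000", "D1500")

#: Representative radial distance for localizing a detection from its
#: category; LT500 uses the 250 m bin midpoint.
REPRESENTATIVE_DISTANCE_M = {"LT500": 250.0, "D500": 500.0,
                             "D1000": 1000.0, "D1500": 1500.0}


@dataclass(frozen=True)
class ListeningPost:
    site_id: str
    post_index: int
    x: float
    y: float
    days_active: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("post coordinates must be finite")
        if len(self.days_active) == 0:
            raise ValueError("days_active must be non-empty")


@dataclass(frozen=True)
class DetectionRecord:
    """One duet heard from one post on one day."""

    site_id: str
    day: int
    post_index: int
    bearing_deg: float
    distance_category: str
    start_min: float
    end_min: float
    female_heard: bool = True
    twitter_phase_heard: bool = False
    n_extra_individuals: int | None = None
    is_repeat: bool = False
    is_male_solo: bool = False
    override_keep: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.bearing_deg < 360.0):
            raise ValueError(f"bearing {self.bearing_deg} outside [0, 360)")
        if self.distance_category not in DISTANCE_CATEGORIES:
            raise ValueError(f"unknown distance category {self.distance_category!r}")
        if self.start_min > self.end_min:
            raise ValueError("start_min must be <= end_min")

    @property
    def bearing_rad(self) -> float:
        return math.radians(self.bearing_deg)


@dataclass
class GroupedDetections:
    """Detections resolved into groups.

    groups : (site_id, day, group_label) -> list of DetectionRecord.
    persistent : (site_id, group_label) -> cross-day persistent group id.
    centroids : (site_id, day, group_label) -> implied (x, y) centroid.
    """

    groups: dict = field(default_factory=dict)
    persistent: dict = field(default_factory=dict)
    centroids: dict = field(default_factory=dict)

    @property
    def n_persistent_groups(self) -> int:
        return len(set(self.persistent.values()))


@dataclass
class CaptureHistory:
    """Binary detection vector over a site's active posts for one group-day.

    omega[i] = 1 iff posts[i] detected the group; bearings_deg maps
    post_index -> observed bearing for exactly the detecting posts.
    """

    site_id: str
    day: int
    group_label: str
    post_indices: tuple
    omega: np.ndarray
    bearings_deg: dict

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=int)
        if self.omega.sum() < 1:
            raise ValueError("capture history must have at least one detection")
        det = {self.post_indices[i] for i in np.flatnonzero(self.omega)}
        if det != set(self.bearings_deg):
            raise ValueError("bearings must be present exactly where omega = 1")


class SchemaError(ValueError):
    pass


_POST_COLS = ["site_id", "post_index", "easting", "northing", "days_active"]
_DET_COLS = ["site_id", "day", "post_index", "bearing_deg", "distance_category",
             "start_min", "end_min", "female_heard", "twitter_heard", "n_extra",
             "is_repeat", "is_male_solo"]


def _require(df: pd.DataFrame, cols, which: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{which} table is missing column(s): {', '.join(missing)}")


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes", "y")
    return bool(v)


def read_survey_tables(posts_source, detections_source):
    """Read and validate posts.csv / detections.csv.

    Returns ``(posts, records, rejected)`` where ``rejected`` is a list of
    ``(table, row_index, message)`` for rows failing validation.  A missing
    required column raises :class:`SchemaError` immediately.
    """
    posts_df = pd.read_csv(posts_source)
    det_df = pd.read_csv(detections_source)
    _require(posts_df, _POST_COLS, "posts")
    _require(det_df, _DET_COLS, "detections")

    posts, rejected = [], []
    for i, row in posts_df.iterrows():
        try:
            days = frozenset(int(d) for d in str(row["days_active"]).split(";") if d)
            posts.append(ListeningPost(str(row["site_id"]), int(row["post_index"]),
                                       float(row["easting"]), float(row["northing"]),
                                       days))
        except (ValueError, TypeError) as exc:
            rejected.append(("posts", int(i), str(exc)))
    _check_posts(posts)

    records = []
    for i, row in det_df.iterrows():
        try:
            n_extra = row["n_extra"]
            n_extra = None if pd.isna(n_extra) else int(n_extra)
            records.append(DetectionRecord(
                site_id=str(row["site_id"]), day=int(row["day"]),
                post_index=int(row["post_index"]),
                bearing_deg=float(row["bearing_deg"]),
                distance_category=str(row["distance_category"]),
                start_min=float(row["start_min"]), end_min=float(row["end_min"]),
                female_heard=_as_bool(row["female_heard"]),
                twitter_phase_heard=_as_bool(row["twitter_heard"]),
                n_extra_individuals=n_extra,
                is_repeat=_as_bool(row["is_repeat"]),
                is_male_solo=_as_bool(row["is_male_solo"]),
            ))
        except (ValueError, TypeError) as exc:
            rejected.append(("detections", int(i), str(exc)))
    return posts, records, rejected


def _check_posts(posts) -> None:
    seen = {}
    for p in posts:
        key = (p.site_id, p.post_index)
        if key in seen:
            raise ValueError(f"duplicate post {key}")
        seen[key] = p
    by_site = {}
    for p in posts:
        by_site.setdefault(p.site_id, []).append(p)
    for site, ps in by_site.items():
        coords = {(p.x, p.y) for p in ps}
        if len(coords) != len(ps):
            raise ValueError(f"posts within site {site} must be pairwise distinct")


def posts_to_frame(posts) -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": [p.site_id for p in posts],
        "post_index": [p.post_index for p in posts],
        "easting": [p.x for p in posts],
        "northing": [p.y for p in posts],
        "days_active": [";".join(str(d) for d in sorted(p.days_active)) for p in posts],
    })


def detections_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": [r.site_id for r in records],
        "day": [r.day for r in records],
        "post_index": [r.post_index for r in records],
        "bearing_deg": [r.bearing_deg for r in records],
        "distance_category": [r.distance_category for r in records],
        "start_min": [r.start_min for r in records],
        "end_min": [r.end_min for r in records],
        "female_heard": [r.female_heard for r in records],
        "twitter_heard": [r.twitter_phase_heard for r in records],
        "n_extra": [r.n_extra_individuals for r in records],
        "is_repeat": [r.is_repeat for r in records],
        "is_male_solo": [r.is_male_solo for r in records],
    })


def implied_location(record: DetectionRecord, post: ListeningPost):
    """Localize a detection at its bearing and the representative distance
    of its category (bearing measured clockwise from north)."""
    r = REPRESENTATIVE_DISTANCE_M[record.distance_category]
    th = record.bearing_rad
    return (post.x + r * math.sin(th), post.y + r * math.cos(th))


def _overlap_min(a_start, a_end, b_start, b_end) -> float:
    return min(a_end, b_end) - max(a_start, b_start)


def _contains(a_start, a_end, b_start, b_end) -> bool:
    return (a_start <= b_start and b_end <= a_end) or (b_start <= a_start and a_end <= b_end)


def filter_detections(records, posts=None, merge_distance_m: float = 500.0,
                      min_overlap_min: float = 1.0):
    """Apply the exclusion rules: drop same-day repeat duets and male solo
    calls, unless rescued.

    A male-solo-flagged record is retained when a retained duet at a
    *different* post of the same site-day overlaps it in time by at least
    ``min_overlap_min`` and (when ``posts`` with coordinates are supplied)
    the two implied locations are within ``merge_distance_m`` — evidence
    that the "solo" was in fact a distant duet whose female part was hard
    to hear.  Records flagged ``override_keep`` are always retained.

    Returns ``(kept, log)`` where ``log`` lists ``(record, reason)`` for
    every dropped record.  Idempotent.
    """
    post_map = {(p.site_id, p.post_index): p for p in posts} if posts else {}
    duets = [r for r in records
             if not r.is_repeat and not r.is_male_solo]
    kept, log = [], []
    for r in records:
        if r.override_keep:
            kept.append(r)
            continue
        if r.is_repeat:
            log.append((r, "repeat duet"))
            continue
        if not r.is_male_solo:
            kept.append(r)
            continue
        if _solo_rescued(r, duets, post_map, merge_distance_m, min_overlap_min):
            kept.append(r)
        else:
            log.append((r, "male solo without corroborating duet"))
    return kept, log


def _solo_rescued(solo, duets, post_map, merge_distance_m, min_overlap_min) -> bool:
    for d in duets:
        if d.site_id != solo.site_id or d.day != solo.day:
            continue
        if d.post_index == solo.post_index:
            continue
        ov = _overlap_min(solo.start_min, solo.end_min, d.start_min, d.end_min)
        if ov < min_overlap_min and not _contains(solo.start_min, solo.end_min,
                                                  d.start_min, d.end_min):
            continue
        if post_map:
            ps = post_map.get((solo.site_id, solo.post_index))
            pd_ = post_map.get((d.site_id, d.post_index))
            if ps is None or pd_ is None:
                raise KeyError(f"detection references unknown post "
                               f"({solo.site_id}, {solo.post_index})")
            xs, ys = implied_location(solo, ps)
            xd, yd = implied_location(d, pd_)
            if math.hypot(xs - xd, ys - yd) >= merge_distance_m:
                continue
        return True
    return False


def assign_group_ids(records, posts, merge_distance_m: float = 500.0,
                     min_overlap_min: float = 1.0) -> GroupedDetections:
    """Resolve filtered detections into same-day groups and persistent
    cross-day identities.

    Same-day: detections are localized (bearing + representative category
    distance) and merged greedily in chronological order — a detection
    joins the first existing group whose centroid is within
    ``merge_distance_m`` and whose call window overlaps its own by at
    least ``min_overlap_min`` minutes (or one window contains the other).
    Detections further apart, or disjoint in time, start new groups
    (groups > 500 m apart are conventionally treated as distinct).

    Cross-day: a day's group inherits the persistent id of the nearest
    same-site group centroid from earlier days within ``merge_distance_m``
    (each persistent id used at most once per day); otherwise it founds a
    new persistent group.

    Deterministic under input row order: processing is sorted by
    (site, day, start time, post index, bearing).
    """
    post_map = {(p.site_id, p.post_index): p for p in posts}
    for r in records:
        if (r.site_id, r.post_index) not in post_map:
            raise KeyError(f"detection references unknown post "
                           f"({r.site_id}, {r.post_index})")

    ordered = sorted(records, key=lambda r: (r.site_id, r.day, r.start_min,
                                             r.post_index, r.bearing_deg))
    out = GroupedDetections()
    next_pid = 0
    # per-site persistent group centroids: site -> list of [pid, sum_x, sum_y, n]
    persistent_cent: dict = {}
    site_days: dict = {}
    for r in ordered:
        site_days.setdefault(r.site_id, set()).add(r.day)

    for site in sorted(site_days):
        label_counter = 0
        persistent_cent.setdefault(site, [])
        for day in sorted(site_days[site]):
            day_recs = [r for r in ordered if r.site_id == site and r.day == day]
            clusters = []  # each: dict(records, xs, ys, t0, t1)
            for r in day_recs:
                x, y = implied_location(r, post_map[(site, r.post_index)])
                placed = False
                for c in clusters:
                    cx = np.mean(c["xs"])
                    cy = np.mean(c["ys"])
                    if math.hypot(x - cx, y - cy) > merge_distance_m:
                        continue
                    ov = _overlap_min(c["t0"], c["t1"], r.start_min, r.end_min)
                    if ov >= min_overlap_min or _contains(c["t0"], c["t1"],
                                                          r.start_min, r.end_min):
                        c["records"].append(r)
                        c["xs"].append(x)
                        c["ys"].append(y)
                        c["t0"] = min(c["t0"], r.start_min)
                        c["t1"] = max(c["t1"], r.end_min)
                        placed = True
                        break
                if not placed:
                    clusters.append({"records": [r], "xs": [x], "ys": [y],
                                     "t0": r.start_min, "t1": r.end_min})
            used_today = set()
            for c in clusters:
                label_counter += 1
                label = f"G{label_counter:03d}"
                cx = float(np.mean(c["xs"]))
                cy = float(np.mean(c["ys"]))
                out.groups[(site, day, label)] = list(c["records"])
                out.centroids[(site, day, label)] = (cx, cy)
                # cross-day identity by nearest prior centroid
                best = None
                for entry in persistent_cent[site]:
                    pid, sx, sy, n = entry
                    if pid in used_today:
                        continue
                    d = math.hypot(cx - sx / n, cy - sy / n)
                    if d <= merge_distance_m and (best is None or d < best[0]):
                        best = (d, entry)
                if best is None:
                    pid = next_pid
                    next_pid += 1
                    persistent_cent[site].append([pid, cx, cy, 1])
                else:
                    entry = best[1]
                    pid = entry[0]
                    entry[1] += cx
                    entry[2] += cy
                    entry[3] += 1
                used_today.add(pid)
                out.persistent[(site, label)] = pid
    return out


def build_capture_histories(grouped: GroupedDetections, posts):
    """One CaptureHistory per (site, day, group), with one omega slot per
    post active that day and bearings carried through for detecting posts."""
    by_site: dict = {}
    for p in posts:
        by_site.setdefault(p.site_id, []).append(p)
    for site in by_site:
        by_site[site].sort(key=lambda p: p.post_index)

    histories = []
    for (site, day, label) in sorted(grouped.groups):
        recs = grouped.groups[(site, day, label)]
        if not recs:
            raise ValueError(f"group ({site}, {day}, {label}) has no detections")
        active = [p for p in by_site.get(site, []) if day in p.days_active]
        if not active:
            raise ValueError(f"no posts active at site {site} on day {day}")
        idx = tuple(p.post_index for p in active)
        omega = np.zeros(len(active), dtype=int)
        bearings: dict = {}
        for r in sorted(recs, key=lambda r: (r.start_min, r.post_index)):
            if r.post_index not in idx:
                raise ValueError(
                    f"detection at post {r.post_index} on day {day} at site "
                    f"{site}, but that post was not active that day")
            i = idx.index(r.post_index)
            omega[i] = 1
            bearings.setdefault(r.post_index, r.bearing_deg)
        histories.append(CaptureHistory(site, day, label, idx, omega, bearings))
    return histories
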