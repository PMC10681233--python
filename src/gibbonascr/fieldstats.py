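"""Descriptive field-survey computations: logging transects, stump and DBH
summaries, and duet-timing histograms.

Logging intensity is assessed on foot: at each of up to six locations per
site, three observers 40 m apart walk parallel 500 m transects, with a
20 m half-width either side of the swath and 20 m surveyed off each end.
Stumps with circumference >= 75 cm are measured and their felling time
estimated to the nearest year.  Multi-stem trees are summarized by a
single effective DBH (root of the summed squared stem DBHs, preserving
basal area).  Duet timing is binned in 10-minute blocks relative to local
sunrise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoggedTree",
    "TransectLayout",
    "DuetEvent",
    "FELLING_CLASSES",
    "transect_footprint_area",
    "effective_dbh",
    "logging_summary",
    "duet_timing_histogram",
]

FELLING_CLASSES = ("<1y", "1y", "2y", "3y", "4y", "5y", ">5y")


@dataclass(frozen=True)
class LoggedTree:
    site_id: str
    species_local_name: str
    stump_height_cm: float | None = None
    stump_diameter_cm: float | None = None  # None = could not be measured
    felling_time_class: str | None = None
    found_on_transect: bool = False
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        if self.stump_diameter_cm is not None and self.stump_diameter_cm < 0:
            raise ValueError("stump diameter must be >= 0 when measured")
        if (self.felling_time_class is not None
                and self.felling_time_class not in FELLING_CLASSES):
            raise ValueError(f"unknown felling class {self.felling_time_class!r}")


@dataclass(frozen=True)
class TransectLayout:
    """One survey location: up to three parallel observer lines.

    The footprint is (length + end extension) x swath width, where the
    swath spans the observer lines (observer_gap_m between neighbours)
    plus a half-width either side.
    """

    n_transects: int = 3
    transect_length_m: float = 500.0
    observer_gap_m: float = 40.0
    half_width_m: float = 20.0
    end_extension_m: float = 20.0

    def __post_init__(self) -> None:
        if self.n_transects not in (1, 2, 3):
            raise ValueError("n_transects must be 1, 2 or 3")
        for v in (self.transect_length_m, self.observer_gap_m,
                  self.half_width_m, self.end_extension_m):
            if v < 0:
                raise ValueError("lengths must be >= 0")


@dataclass(frozen=True)
class DuetEvent:
    group_id: str
    day: int
    start_min_rel_sunrise: float
    is_first_duet: bool = True
    override_keep: bool = False


def transect_footprint_area(layout: TransectLayout) -> float:
    """Surveyed area (m^2) of one transect location.

    Full design (3 observers, 500 m): (500 + 20) x ((3-1)*40 + 2*20) = 62,400 m^2.
    Partial transects substitute the completed length.
    """
    width = (layout.n_transects - 1) * layout.observer_gap_m + 2 * layout.half_width_m
    length = layout.transect_length_m + layout.end_extension_m
    return float(length * width)


def effective_dbh(stem_dbhs) -> float:
    """Single-tree DBH equivalent of a multi-stem tree: sqrt(sum d_i^2).

    Preserves total basal area; equals the stem DBH for a single stem and
    is never below the largest stem.
    """
    stems = list(stem_dbhs)
    if not stems:
        raise ValueError("need at least one stem")
    if any(d <= 0 for d in stems):
        raise ValueError("stem DBH values must be > 0")
    return math.sqrt(sum(d * d for d in stems))


def logging_summary(trees) -> dict:
    """Tabulate logged trees: species ranking, felling-time distributions,
    per-species stump statistics.

    Returns a dict of DataFrames:

    * ``species`` — frequency ranking (descending).
    * ``felling`` — counts and percentages per felling class, for transect
      trees and for all trees; trees without a felling estimate are
      reported in a separate ``missing`` row, excluded from percentages.
    * ``stumps`` — per-species mean/SD of stump height and diameter;
      unmeasurable stumps are excluded from the diameter statistics but
      kept in species counts.
    """
    if not trees:
        return {"species": pd.DataFrame(), "felling": pd.DataFrame(),
                "stumps": pd.DataFrame()}
    df = pd.DataFrame({
        "species": [t.species_local_name for t in trees],
        "height": [t.stump_height_cm for t in trees],
        "diameter": [t.stump_diameter_cm for t in trees],
        "felling": [t.felling_time_class for t in trees],
        "on_transect": [t.found_on_transect for t in trees],
    })

    species = (df.groupby("species").size().sort_values(ascending=False)
               .rename("frequency").reset_index())
    species.index = np.arange(1, len(species) + 1)
    species.index.name = "rank"

    rows = []
    for label, sub in (("transect", df[df.on_transect]), ("all", df)):
        known = sub[sub.felling.notna()]
        total = len(known)
        for cls in FELLING_CLASSES:
            cnt = int((known.felling == cls).sum())
            rows.append({"column": label, "felling_class": cls, "count": cnt,
                         "percent": 100.0 * cnt / total if total else float("nan")})
        rows.append({"column": label, "felling_class": "missing",
                     "count": int(sub.felling.isna().sum()),
                     "percent": float("nan")})
    felling = pd.DataFrame(rows)

    stats = []
    for sp, sub in df.groupby("species"):
        meas = sub[sub.diameter.notna()]
        h = sub[sub.height.notna()]
        stats.append({
            "species": sp, "n_total": len(sub),
            "n_height": len(h),
            "height_mean": h.height.mean() if len(h) else float("nan"),
            "height_sd": h.height.std(ddof=1) if len(h) > 1 else float("nan"),
            "n_diameter": len(meas),
            "diameter_mean": meas.diameter.mean() if len(meas) else float("nan"),
            "diameter_sd": meas.diameter.std(ddof=1) if len(meas) > 1 else float("nan"),
        })
    stumps = pd.DataFrame(stats).set_index("species")
    return {"species": species, "felling": felling, "stumps": stumps}


def duet_timing_histogram(events, bin_min: float = 10.0,
                          window: tuple = (-30.0, 30.0)) -> dict:
    """Histogram of first-duet start times relative to sunrise.

    Bins are left-open right-closed and labelled by their right endpoint:
    a duet starting at x sits in bin ``bin_min * ceil(x / bin_min)`` (so
    -10 < x <= 0 lands in bin "0").  Only first duets are counted, plus
    any events explicitly flagged ``override_keep`` (a repeat can be the
    representative duet when the true first fell outside the survey
    window).

    Returns counts per bin, the modal bin and its proportion, and the
    proportion inside ``window`` (open-left, closed-right; default the
    hour starting 30 minutes before sunrise).
    """
    if bin_min <= 0:
        raise ValueError("bin_min must be > 0")
    kept = [e for e in events if e.is_first_duet or e.override_keep]
    times = np.array([e.start_min_rel_sunrise for e in kept], dtype=float)
    n = times.size
    if n == 0:
        return {"counts": pd.Series(dtype=int), "n": 0,
                "modal_bin": None, "modal_proportion": float("nan"),
                "window": window, "window_proportion": float("nan")}
    labels = bin_min * np.ceil(times / bin_min)
    labels[labels == 0.0] = 0.0  # avoid -0.0 labels
    counts = pd.Series(labels).value_counts().sort_index()
    counts.index = counts.index.astype(float)
    modal_bin = float(counts.idxmax())
    modal_count = int(counts.max())
    lo, hi = window
    in_window = int(np.sum((times > lo) & (times <= hi)))
    return {
        "counts": counts.astype(int),
        "n": int(n),
        "modal_bin": modal_bin,
        "modal_count": modal_count,
        "modal_proportion": modal_count / n,
        "window": window,
        "window_count": in_window,
        "window_proportion": in_window / n,
    }
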