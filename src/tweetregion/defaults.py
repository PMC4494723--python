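"""Shipped default filter configuration for the Mississippi/Alabama use case.

The triangulation criteria mirror the published regional-criterion table for
the February 2013 Hattiesburg EF-4 tornado: three biography rows, five
location rows, and one tweet (news-mention) row.  The news-handle list is a
plausible editable placeholder -- the original outlet list was not published.
ZIP membership is expressed as the contiguous 5-digit ranges of the two
states, a convention users can override with an explicit list.
"""

from __future__ import annotations

from datetime import datetime, timezone
from importlib import resources

#: first tornado touchdown, 2013-02-10 17:00 CST expressed in UTC
DEFAULT_EVENT_TIME = datetime(2013, 2, 10, 23, 0, tzinfo=timezone.utc)

#: UTC offset of the event locale (CST), hours
DEFAULT_UTC_OFFSET_H = -6

STATE_CITY_TERMS = ("mississippi", "alabama", "hattiesburg", "birmingham")
UNIVERSITY_TERMS = ("usm", "ole miss")
CHANT_TERMS = ("smttt",)
STATE_ABBREV_TERMS = ("ms", "al")

#: contiguous 5-digit ZIP ranges for Mississippi and Alabama
DEFAULT_ZIP_RANGES: tuple[tuple[int, int], ...] = ((38601, 39776), (35004, 36925))

#: editable placeholder handles for regional news outlets (TV/radio/print)
DEFAULT_NEWS_HANDLES = (
    "wdam",
    "wjtv",
    "wapt",
    "wlbt",
    "hattiesburgamer",
    "clarionledger",
    "aldotcom",
    "wbrcnews",
    "msema",
)

#: disaster/relief keywords and hashtags for the broad first-pass extraction
DEFAULT_KEYWORDS = (
    "tornado",
    "storm",
    "shelter",
    "damage",
    "debris",
    "relief",
    "hattiesburg",
    "petal",
    "mississippi",
    "alabama",
)
DEFAULT_HASHTAGS = (
    "hattiesburg",
    "mstornado",
    "prayforhattiesburg",
    "hattiesburgtornado",
    "mswx",
    "alwx",
)

#: homonym place names purged after the broad extraction
DEFAULT_EXCLUSION_PLACES = ("petaling",)


def region_polygons_path():
    """Path to the shipped coarse two-state region polygons (synthetic
    rectangles standing in for the real state boundaries)."""
    return resources.files("tweetregion.data") / "region_ms_al_synthetic.geojson"
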