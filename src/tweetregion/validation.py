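"""GPS confirmation, survey sample sizing, and quality-assessment sampling.

Regional verdicts are cross-checked against the geotags users actually
emitted: a regional user is *GPS-confirmed* when at least one of their
geotags falls inside the target region polygons, and *location-consistent*
when unconfirmed but their stated location still matches a location
criterion row (travellers who self-identify with the region).  Confirmed
plus consistent users over all GPS-active users is the "likely regional"
accuracy of the triangulation.

Sample sizes for manual review follow the standard normal-approximation
formula for a proportion with finite-population correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Point, shape
from statsmodels.stats.proportion import proportion_confint

from tweetregion.ingest import TweetRecord
from tweetregion.textmatch import any_term_matches


class ConfigurationError(ValueError):
    pass


def load_region_polygons(source: str | Path | Mapping) -> dict[str, object]:
    """Read a GeoJSON FeatureCollection into ``{region_id: shapely geometry}``.

    Each feature needs a polygonal geometry and a ``region_id`` property
    (falling back to ``name`` or a running index).
    """
    if isinstance(source, Mapping):
        gj = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ConfigurationError("expected a GeoJSON FeatureCollection")
    polygons: dict[str, object] = {}
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ConfigurationError(f"feature {i}: not polygonal")
        if not geom.is_valid:
            raise ConfigurationError(f"feature {i}: invalid polygon")
        props = feat.get("properties") or {}
        region_id = str(props.get("region_id") or props.get("name") or i)
        polygons[region_id] = geom
    if not polygons:
        raise ConfigurationError("no polygon features found")
    return polygons


def point_in_region(
    lon: float, lat: float, polygons: Mapping[str, object]
) -> str | None:
    """Containing region id for a WGS84 point, or ``None``.

    Containment is even-odd with boundary points counting as inside; holes
    are honoured.  Region ids are probed in sorted order so ties on shared
    boundaries resolve deterministically.
    """
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"coordinates out of range: lon={lon}, lat={lat}")
    pt = Point(lon, lat)
    for region_id in sorted(polygons):
        if polygons[region_id].covers(pt):
            return region_id
    return None


@dataclass(frozen=True)
class ValidationReport:
    """GPS confirmation tallies and the likely-regional accuracy."""

    gps_users: int
    gps_confirmed_users: int
    location_consistent_users: int
    likely_regional_users: int
    likely_regional_accuracy_pct: float | None
    gps_tweets: int
    gps_tweets_in_region: int

    def __post_init__(self):
        if self.gps_confirmed_users > self.gps_users:
            raise ValueError("confirmed users cannot exceed GPS users")
        if (
            self.likely_regional_users
            != self.gps_confirmed_users + self.location_consistent_users
        ):
            raise ValueError("likely regional must equal confirmed + consistent")
        if self.likely_regional_users > self.gps_users:
            raise ValueError("likely regional cannot exceed GPS users")
        if self.gps_tweets_in_region > self.gps_tweets:
            raise ValueError("in-region GPS tweets cannot exceed GPS tweets")

    @classmethod
    def from_counts(
        cls,
        gps_users: int,
        gps_confirmed_users: int,
        location_consistent_users: int,
        gps_tweets: int = 0,
        gps_tweets_in_region: int = 0,
    ) -> "ValidationReport":
        """Assemble a report from raw tallies, deriving the combined
        likely-regional count and accuracy percentage."""
        likely = gps_confirmed_users + location_consistent_users
        pct = 100.0 * likely / gps_users if gps_users else None
        return cls(
            gps_users=gps_users,
            gps_confirmed_users=gps_confirmed_users,
            location_consistent_users=location_consistent_users,
            likely_regional_users=likely,
            likely_regional_accuracy_pct=pct,
            gps_tweets=gps_tweets,
            gps_tweets_in_region=gps_tweets_in_region,
        )


def gps_validation_report(
    assignments,
    records: Sequence[TweetRecord],
    polygons: Mapping[str, object],
    location_criteria=(),
) -> ValidationReport:
    """GPS-confirm regional users against the region polygons.

    ``assignments`` are the regional users' triangulation verdicts;
    ``location_criteria`` are the location-category criterion rows used for
    the traveller fallback.  When no regional user has a geotag the accuracy
    is ``None`` (flagged undefined).
    """
    regional = {a.user_id for a in assignments if a.is_regional}
    geo_by_user: dict[str, list[tuple[float, float]]] = {}
    latest_loc: dict[str, tuple] = {}
    for rec in records:
        if rec.user_id not in regional:
            continue
        if rec.geo is not None:
            geo_by_user.setdefault(rec.user_id, []).append(rec.geo)
        prev = latest_loc.get(rec.user_id)
        if prev is None or rec.timestamp >= prev[0]:
            latest_loc[rec.user_id] = (rec.timestamp, rec.location_string)

    gps_users = len(geo_by_user)
    confirmed = 0
    gps_tweets = 0
    gps_tweets_in = 0
    unconfirmed: list[str] = []
    for uid, geos in geo_by_user.items():
        any_in = False
        for lat, lon in geos:
            gps_tweets += 1
            if point_in_region(lon, lat, polygons) is not None:
                gps_tweets_in += 1
                any_in = True
        if any_in:
            confirmed += 1
        else:
            unconfirmed.append(uid)

    consistent = 0
    loc_rows = [c for c in location_criteria if getattr(c, "category", "location") == "location"]
    for uid in unconfirmed:
        loc = latest_loc.get(uid, (None, None))[1]
        if not loc:
            continue
        for crit in loc_rows:
            if crit.terms and any_term_matches(crit.terms, loc):
                consistent += 1
                break
            if crit.zip_ranges:
                from tweetregion.triangulation import _zip_match

                if _zip_match(loc, crit.zip_ranges):
                    consistent += 1
                    break
    return ValidationReport.from_counts(
        gps_users, confirmed, consistent, gps_tweets, gps_tweets_in
    )


def required_sample_size(
    population: int,
    confidence: float,
    moe: float,
    p: float = 0.5,
) -> int:
    """Required simple-random-sample size for a proportion.

    ``n0 = z^2 p(1-p) / moe^2`` with ``z`` the two-sided normal quantile at
    the given confidence, then finite-population corrected as
    ``n = n0 / (1 + (n0 - 1)/N)``; returned as the ceiling, capped at ``N``.
    The worst-case variance convention ``p = 0.5`` is the default.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if not (0.0 < moe < 1.0):
        raise ValueError("moe must be in (0, 1)")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if population < 1:
        raise ValueError("population must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n0 = z * z * p * (1.0 - p) / (moe * moe)
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return min(population, math.ceil(n))


@dataclass(frozen=True)
class QASample:
    """A reproducible simple random sample drawn for manual review."""

    sampled_user_ids: tuple[str, ...]
    stratum: str
    seed: int
    judgments: Mapping[str, str] | None = None  # user_id -> "pass" | "fail"

    def __post_init__(self):
        if len(set(self.sampled_user_ids)) != len(self.sampled_user_ids):
            raise ValueError("sample contains duplicate ids")

    def with_judgments(self, judgments: Mapping[str, str]) -> "QASample":
        return QASample(self.sampled_user_ids, self.stratum, self.seed, dict(judgments))


def draw_sample(
    ids: Sequence[str], n: int, seed: int, stratum: str = "regional"
) -> QASample:
    """Simple random sample of ``n`` ids without replacement, seeded."""
    ids = list(ids)
    if n > len(ids):
        raise ValueError(f"cannot sample {n} from {len(ids)} ids")
    if len(set(ids)) != len(ids):
        raise ValueError("ids contain duplicates")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return QASample(tuple(ids[i] for i in chosen), stratum, seed)


def qa_error_rate(
    sample: QASample, confidence: float = 0.99
) -> tuple[float, tuple[float, float]]:
    """Error proportion of a judged QA sample with a Wilson score interval."""
    if sample.judgments is None:
        raise ValueError("sample has no judgments")
    missing = set(sample.sampled_user_ids) - set(sample.judgments)
    if missing:
        raise ValueError(f"missing judgments for {len(missing)} users")
    size = len(sample.sampled_user_ids)
    if size == 0:
        raise ValueError("empty sample")
    fails = sum(
        1 for uid in sample.sampled_user_ids if sample.judgments[uid] == "fail"
    )
    lo, hi = proportion_confint(fails, size, alpha=1.0 - confidence, method="wilson")
    return fails / size, (float(lo), float(hi))
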