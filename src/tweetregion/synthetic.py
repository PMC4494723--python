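"""Ground-truth-labelled synthetic tweet corpora.

The generator emulates the statistical structure the pipeline assumes about
a localized-disaster corpus: a mixture of truly regional and non-regional
users, per-user tweet times from an inhomogeneous Poisson process (sinusoidal
diurnal cycle times a multiplicative post-event spike that decays with a
configurable half-life for regional users), profile biographies/locations
drawn from the filter term pools with configurable missingness, geotags
inside the region polygons apart from a small noise fraction, planted
retweets/hashtags/news mentions, and a homonym confounder population whose
location string ("Petaling Jaya"-style) defeats substring filters.

Default parameters are calibrated to the 2013 Hattiesburg tornado corpus
regime: regional users are ~31% of users, tweet ~2.4 times/user/day, ~34% of
tweets are retweets, ~24% carry a hashtag, ~6% of users emit geotags with
~3% of geotags falling outside the region, and ~14%/~4% of regional users
leave the biography/location blank.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tweetregion import defaults
from tweetregion.triangulation import RegionalAssignment

_DAY_H = 24.0

#: innocuous profile text for non-regional users (must defeat the filters)
_NEUTRAL_BIOS = (
    "coffee enthusiast and amateur photographer",
    "dog parent, runner, occasional baker",
    "software tinkerer",
    "music and movies",
    "just here for the memes",
)
_NEUTRAL_LOCATIONS = (
    "Portland, OR",
    "Denver, CO",
    "Toronto",
    "London",
    "Springfield",
)
_HASHTAG_POOL = ("tornado", "mswx", "weather", "news", "prayers")
_SOURCE_POOL = (
    ("Twitter for iPhone", 0.38),
    ("Twitter for Android", 0.25),
    ("Twitter for BlackBerry", 0.08),
    ("Twitter Web Client", 0.2),
    ("TweetDeck", 0.05),
    ("Instagram", 0.04),
)
_TZ_REGIONAL = (
    ("Central Time (US & Canada)", 0.5),
    (None, 0.27),
    ("Mountain Time (US & Canada)", 0.08),
    ("Eastern Time (US & Canada)", 0.07),
    ("Pacific Time (US & Canada)", 0.03),
    ("Quito", 0.05),
)
_TZ_NONREGIONAL = (
    ("Eastern Time (US & Canada)", 0.3),
    (None, 0.3),
    ("Pacific Time (US & Canada)", 0.2),
    ("London", 0.2),
)

#: sampling rectangles (lon_min, lon_max, lat_min, lat_max)
_IN_REGION_BOX = (-91.0, -85.5, 30.8, 34.5)  # inside the two-state fixtures
_OUT_REGION_BOX = (-100.0, -95.0, 38.0, 42.0)
_CONFOUNDER_POINT = (101.6, 3.1)  # Petaling Jaya, Malaysia


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a ground-truth corpus (all rates in [0,1])."""

    n_users: int = 2000
    regional_fraction: float = 0.31
    span_start: datetime = defaults.DEFAULT_EVENT_TIME - timedelta(hours=50)
    span_end: datetime = defaults.DEFAULT_EVENT_TIME + timedelta(hours=46)
    event_time: datetime = defaults.DEFAULT_EVENT_TIME
    base_rate: float = 2.4  # tweets / user / day
    diurnal_amplitude: float = 0.6
    event_spike_multiplier: float = 5.0
    spike_halflife_h: float = 12.0
    retweet_fraction: float = 0.335
    hashtag_fraction: float = 0.238
    news_mention_rate: float = 0.05
    gps_enabled_fraction: float = 0.061
    gps_tweet_rate: float = 0.47
    gps_noise_outside_fraction: float = 0.027
    bio_term_pool: tuple[str, ...] = (
        defaults.STATE_CITY_TERMS + defaults.UNIVERSITY_TERMS + defaults.CHANT_TERMS
    )
    location_term_pool: tuple[str, ...] = (
        "Hattiesburg, MS",
        "Mississippi",
        "Birmingham, AL",
        "Alabama",
        "39401",
        "Ole Miss country",
        "USM",
        "SMTTT",
    )
    news_handle_pool: tuple[str, ...] = defaults.DEFAULT_NEWS_HANDLES
    confounder_locations: tuple[str, ...] = ("Petaling Jaya",)
    confounder_fraction: float = 0.05
    missing_bio_fraction: float = 0.143
    missing_location_fraction: float = 0.038
    utc_offset_h: float = defaults.DEFAULT_UTC_OFFSET_H
    seed: int = 0

    def __post_init__(self):
        for name in (
            "regional_fraction",
            "retweet_fraction",
            "hashtag_fraction",
            "news_mention_rate",
            "gps_enabled_fraction",
            "gps_tweet_rate",
            "gps_noise_outside_fraction",
            "confounder_fraction",
            "missing_bio_fraction",
            "missing_location_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.span_start <= self.event_time <= self.span_end):
            raise ValueError("event_time must lie within the span")
        if self.event_spike_multiplier < 1.0:
            raise ValueError("event_spike_multiplier must be >= 1")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.regional_fraction > 0 and not (
            self.bio_term_pool and self.location_term_pool and self.news_handle_pool
        ):
            raise ValueError("term pools must be nonempty for regional users")


@dataclass
class GroundTruth:
    """Planted labels and tallies consistent with the emitted corpus."""

    regional_users: frozenset[str]
    all_users: frozenset[str]
    confounder_users: frozenset[str]
    record_in_region_geo: dict[str, bool]  # tweet_id -> geotag inside region?
    window_tallies: dict[str, dict[str, int]]  # "pre"/"post" regional-record tallies


@dataclass(frozen=True)
class PipelineScore:
    """User-level confusion-matrix summary of a triangulation run."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None


def _pick(rng: np.random.Generator, weighted: Sequence[tuple]) -> object:
    items = [w[0] for w in weighted]
    probs = np.array([w[1] for w in weighted], dtype=float)
    return items[rng.choice(len(items), p=probs / probs.sum())]


def _diurnal(hour_local: float, amplitude: float) -> float:
    # peak mid-afternoon (15:00 local), trough overnight
    return 1.0 + amplitude * math.cos(2.0 * math.pi * (hour_local - 15.0) / _DAY_H)


def _spike(dt_h: float, multiplier: float, halflife_h: float) -> float:
    if dt_h < 0 or multiplier <= 1.0:
        return 1.0
    return 1.0 + (multiplier - 1.0) * 2.0 ** (-dt_h / halflife_h)


def _user_times(
    rng: np.random.Generator, cfg: SyntheticConfig, regional: bool
) -> list[datetime]:
    """Tweet instants from the thinned inhomogeneous Poisson process."""
    span_h = (cfg.span_end - cfg.span_start) / timedelta(hours=1)
    lam_base = cfg.base_rate / _DAY_H  # per hour
    lam_max = lam_base * (1.0 + cfg.diurnal_amplitude)
    if regional:
        lam_max *= cfg.event_spike_multiplier
    n_cand = rng.poisson(lam_max * span_h)
    offsets = np.sort(rng.uniform(0.0, span_h, size=n_cand))
    times: list[datetime] = []
    for off in offsets:
        t = cfg.span_start + timedelta(hours=float(off))
        hour_local = ((t - t.replace(hour=0, minute=0, second=0, microsecond=0))
                      / timedelta(hours=1) + cfg.utc_offset_h) % _DAY_H
        lam = lam_base * _diurnal(hour_local, cfg.diurnal_amplitude)
        if regional:
            dt_h = (t - cfg.event_time) / timedelta(hours=1)
            lam *= _spike(dt_h, cfg.event_spike_multiplier, cfg.spike_halflife_h)
        if rng.uniform() * lam_max < lam:
            times.append(t)
    if not times:  # every simulated account is active at least once
        times.append(
            cfg.span_start
            + timedelta(hours=float(rng.uniform(0.0, span_h)))
        )
    return times


def _sample_box(rng: np.random.Generator, box) -> tuple[float, float]:
    lon = float(rng.uniform(box[0], box[1]))
    lat = float(rng.uniform(box[2], box[3]))
    return lat, lon


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[dict], GroundTruth]:
    """Generate a JSON-lines-ready corpus and its ground truth.

    Returns the corpus as a list of per-tweet dicts in the dialect
    :func:`tweetregion.ingest.read_activity_stream` reads by default, plus a
    :class:`GroundTruth` sidecar.  Fully reproducible: identical configs
    (including seed) produce identical corpora; per-user generators are
    namespaced so editing one parameter does not reshuffle unrelated users.
    """
    cfg = config
    master = np.random.default_rng(cfg.seed)
    n_regional = int(round(cfg.n_users * cfg.regional_fraction))
    is_regional_arr = np.zeros(cfg.n_users, dtype=bool)
    idx = master.permutation(cfg.n_users)[:n_regional]
    is_regional_arr[idx] = True

    corpus: list[dict] = []
    regional_users: set[str] = set()
    confounders: set[str] = set()
    record_in_region: dict[str, bool] = {}
    planted = {
        "pre": {"tweets": 0, "retweets": 0, "hashtag_tweets": 0, "gps_tweets": 0},
        "post": {"tweets": 0, "retweets": 0, "hashtag_tweets": 0, "gps_tweets": 0},
    }

    for u in range(cfg.n_users):
        rng = np.random.default_rng([cfg.seed, u])
        uid = f"u{u:06d}"
        regional = bool(is_regional_arr[u])
        if regional:
            regional_users.add(uid)

        # --- static profile -------------------------------------------------
        bio: str | None
        location: str | None
        if regional:
            bio = (
                f"proud {rng.choice(cfg.bio_term_pool)} fan"
                if rng.uniform() >= cfg.missing_bio_fraction
                else None
            )
            location = (
                str(rng.choice(cfg.location_term_pool))
                if rng.uniform() >= cfg.missing_location_fraction
                else None
            )
            tz = _pick(rng, _TZ_REGIONAL)
        else:
            bio = str(rng.choice(_NEUTRAL_BIOS)) if rng.uniform() > 0.2 else None
            if cfg.confounder_locations and rng.uniform() < cfg.confounder_fraction:
                location = str(rng.choice(cfg.confounder_locations))
                confounders.add(uid)
            else:
                location = (
                    str(rng.choice(_NEUTRAL_LOCATIONS))
                    if rng.uniform() > 0.3
                    else None
                )
            tz = _pick(rng, _TZ_NONREGIONAL)
        force_news_mention = regional and bio is None and location is None

        gps_enabled = rng.uniform() < cfg.gps_enabled_fraction
        followers = int(rng.lognormal(mean=5.6, sigma=1.2))
        friends = int(rng.lognormal(mean=5.6, sigma=1.0))
        verified = bool(rng.uniform() < 0.001)
        account_created = cfg.event_time - timedelta(
            days=float(rng.uniform(60, 1600))
        )
        influence = float(np.clip(rng.normal(33.0, 12.0), 0.0, 100.0))

        # --- tweets ---------------------------------------------------------
        times = _user_times(rng, cfg, regional)
        news_idx = int(rng.integers(len(times))) if force_news_mention else -1
        for i, t in enumerate(times):
            tid = f"t{u:06d}_{i:04d}"
            text_parts = ["synthetic status update"]
            hashtags: list[str] = []
            mentions: list[str] = []
            is_rt = bool(rng.uniform() < cfg.retweet_fraction)
            rt_user = None
            if is_rt:
                rt_user = (
                    str(rng.choice(cfg.news_handle_pool))
                    if regional and rng.uniform() < cfg.news_mention_rate
                    else f"u{int(rng.integers(cfg.n_users)):06d}"
                )
                mentions.append(rt_user)
                text_parts.insert(0, f"RT @{rt_user}:")
            if rng.uniform() < cfg.hashtag_fraction:
                tag = str(rng.choice(_HASHTAG_POOL))
                hashtags.append(tag)
                text_parts.append(f"#{tag}")
            if regional and not is_rt and (
                rng.uniform() < cfg.news_mention_rate or i == news_idx
            ):
                handle = str(rng.choice(cfg.news_handle_pool))
                mentions.append(handle)
                text_parts.append(f"@{handle}")

            lat = lon = None
            if gps_enabled and rng.uniform() < cfg.gps_tweet_rate:
                if regional:
                    outside = rng.uniform() < cfg.gps_noise_outside_fraction
                    lat, lon = _sample_box(
                        rng, _OUT_REGION_BOX if outside else _IN_REGION_BOX
                    )
                    record_in_region[tid] = not outside
                elif uid in confounders:
                    lon, lat = _CONFOUNDER_POINT
                    lat, lon = float(lat), float(lon)
                    record_in_region[tid] = False
                else:
                    lat, lon = _sample_box(rng, _OUT_REGION_BOX)
                    record_in_region[tid] = False

            rec = {
                "id": tid,
                "user_id": uid,
                "created_at": t.isoformat(),
                "text": " ".join(text_parts),
                "hashtags": hashtags,
                "mentions": mentions,
                "is_retweet": is_rt,
                "retweeted_user": rt_user,
                "bio": bio,
                "location": location,
                "time_zone": tz,
                "lat": lat,
                "lon": lon,
                "source": _pick(rng, _SOURCE_POOL),
                "lang": "en" if rng.uniform() < 0.95 else "es",
                "verified": verified,
                "followers": followers,
                "friends": friends,
                "account_created": account_created.isoformat(),
                "influence": round(influence, 1),
            }
            corpus.append(rec)

            if regional:
                window = "pre" if t < cfg.event_time else "post"
                planted[window]["tweets"] += 1
                planted[window]["retweets"] += int(is_rt)
                planted[window]["hashtag_tweets"] += int(bool(hashtags))
                planted[window]["gps_tweets"] += int(lat is not None)

    corpus.sort(key=lambda r: (r["created_at"], r["id"]))

    # self-consistency: planted tallies must equal a recount over the corpus
    recount = {
        k: {"tweets": 0, "retweets": 0, "hashtag_tweets": 0, "gps_tweets": 0}
        for k in ("pre", "post")
    }
    for rec in corpus:
        if rec["user_id"] not in regional_users:
            continue
        w = "pre" if datetime.fromisoformat(rec["created_at"]) < cfg.event_time else "post"
        recount[w]["tweets"] += 1
        recount[w]["retweets"] += int(rec["is_retweet"])
        recount[w]["hashtag_tweets"] += int(bool(rec["hashtags"]))
        recount[w]["gps_tweets"] += int(rec["lat"] is not None)
    assert recount == planted, "planted tallies diverge from emitted corpus"

    truth = GroundTruth(
        regional_users=frozenset(regional_users),
        all_users=frozenset(f"u{u:06d}" for u in range(cfg.n_users)),
        confounder_users=frozenset(confounders),
        record_in_region_geo=record_in_region,
        window_tallies=planted,
    )
    return corpus, truth


def write_corpus(corpus: Sequence[Mapping], path: str | Path) -> int:
    """Write a generated corpus as JSON-lines; returns lines written."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return len(corpus)


def evaluate_pipeline(
    assignments: Sequence[RegionalAssignment], truth: GroundTruth
) -> PipelineScore:
    """Confusion-matrix score of triangulation verdicts against the truth.

    Users absent from ``assignments`` count as predicted non-regional.
    Assignment ids must all exist in the truth.
    """
    predicted = {a.user_id for a in assignments if a.is_regional}
    unknown = {a.user_id for a in assignments} - set(truth.all_users)
    if unknown:
        raise ValueError(f"assignments reference unknown users: {sorted(unknown)[:5]}")
    actual = set(truth.regional_users)
    universe = set(truth.all_users)
    tp = len(predicted & actual)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    tn = len(universe) - tp - fp - fn
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return PipelineScore(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall)
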