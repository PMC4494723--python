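"""Event-centred window splitting and descriptive activity summaries.

The analysis span is anchored on the event instant: a pre window reaching
back ``pre_start_offset_h`` hours and a post window reaching forward
``post_end_offset_h`` hours, split at ``split_offset_h`` (default at impact).
The shipped default is the 96-hour span from -50 h to +46 h -- two 48-hour
windows shifted 2 hours leftward so the pre window captures the activity
just before impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

from tweetregion import defaults
from tweetregion.ingest import TweetRecord
from tweetregion.triangulation import latest_record

METRICS = ("tweets", "retweets", "hashtag_tweets")


@dataclass(frozen=True)
class EventWindowSpec:
    """Event-anchored pre/post window geometry (offsets in hours)."""

    event_time: datetime = defaults.DEFAULT_EVENT_TIME
    pre_start_offset_h: float = 50.0
    split_offset_h: float = 0.0
    post_end_offset_h: float = 46.0

    def __post_init__(self):
        if not (-self.pre_start_offset_h < self.split_offset_h < self.post_end_offset_h):
            raise ValueError("window offsets must satisfy -pre < split < post")
        if self.event_time.tzinfo is None:
            raise ValueError("event_time must be timezone-aware")

    @property
    def pre_start(self) -> datetime:
        return self.event_time - timedelta(hours=self.pre_start_offset_h)

    @property
    def split(self) -> datetime:
        return self.event_time + timedelta(hours=self.split_offset_h)

    @property
    def post_end(self) -> datetime:
        return self.event_time + timedelta(hours=self.post_end_offset_h)


@dataclass(frozen=True)
class WindowSummary:
    """Per-window totals over tweets and means over distinct users."""

    users: int = 0
    tweets: int = 0
    retweets: int = 0
    hashtag_tweets: int = 0
    gps_tweets: int = 0
    application_types: int = 0
    verified_users: int = 0
    languages: int = 0
    mean_account_length_days: float | None = None
    mean_followers: float | None = None
    mean_influence: float | None = None
    mean_friends: float | None = None

    def __post_init__(self):
        for name in ("retweets", "hashtag_tweets", "gps_tweets"):
            if getattr(self, name) > self.tweets:
                raise ValueError(f"{name} cannot exceed tweets")
        if self.tweets >= 1 and self.users < 1:
            raise ValueError("a nonempty window has at least one user")


@dataclass(frozen=True)
class CombinedTotals:
    """Field-wise sums of two window summaries.

    ``user_windows`` sums the two windows' distinct-user counts and so
    double-counts individuals active in both windows; it is a window-level
    tally, not a distinct-user total.
    """

    tweets: int
    user_windows: int
    retweets: int
    hashtag_tweets: int
    gps_tweets: int


@dataclass(frozen=True)
class HourlySeries:
    """Counts of one activity metric per hour offset from the event."""

    metric: str
    hour_offsets: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if len(self.hour_offsets) != len(self.counts):
            raise ValueError("offsets and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")


def split_windows(
    records: Sequence[TweetRecord], spec: EventWindowSpec
) -> tuple[list[TweetRecord], list[TweetRecord], list[TweetRecord]]:
    """Partition records into (pre, post, outside) by timestamp.

    Pre is ``[event - pre_start_offset, event + split_offset)``; post is
    ``[event + split_offset, event + post_end_offset)``; half-open on the
    right, so a record exactly at the split instant lands in post.
    """
    pre: list[TweetRecord] = []
    post: list[TweetRecord] = []
    outside: list[TweetRecord] = []
    for rec in records:
        t = rec.timestamp
        if spec.pre_start <= t < spec.split:
            pre.append(rec)
        elif spec.split <= t < spec.post_end:
            post.append(rec)
        else:
            outside.append(rec)
    return pre, post, outside


def window_summary(
    records: Sequence[TweetRecord], reference_time: datetime | None = None
) -> WindowSummary:
    """Descriptive summary of one window's records.

    Totals count tweets; user-level means are taken over each distinct
    user's latest record in the window, with account length measured back
    from ``reference_time`` (users missing a field are dropped from that
    mean).  An empty window yields all-zero counts and ``None`` means.
    """
    if not records:
        return WindowSummary()
    by_user: dict[str, list[TweetRecord]] = {}
    for rec in records:
        by_user.setdefault(rec.user_id, []).append(rec)
    latest = {uid: latest_record(recs) for uid, recs in by_user.items()}
    if reference_time is None:
        reference_time = max(r.timestamp for r in records)

    def _mean(values):
        values = [v for v in values if v is not None]
        return sum(values) / len(values) if values else None

    return WindowSummary(
        users=len(by_user),
        tweets=len(records),
        retweets=sum(1 for r in records if r.is_retweet),
        hashtag_tweets=sum(1 for r in records if r.hashtags),
        gps_tweets=sum(1 for r in records if r.geo is not None),
        application_types=len({r.source_app for r in records if r.source_app}),
        verified_users=sum(1 for r in latest.values() if r.verified),
        languages=len({r.language for r in records if r.language}),
        mean_account_length_days=_mean(
            (reference_time - r.account_created) / timedelta(days=1)
            if r.account_created
            else None
            for r in latest.values()
        ),
        mean_followers=_mean(r.followers for r in latest.values()),
        mean_influence=_mean(r.influence_score for r in latest.values()),
        mean_friends=_mean(r.friends for r in latest.values()),
    )


def combined_totals(pre: WindowSummary, post: WindowSummary) -> CombinedTotals:
    """Sum the additive fields of the pre and post summaries."""
    return CombinedTotals(
        tweets=pre.tweets + post.tweets,
        user_windows=pre.users + post.users,
        retweets=pre.retweets + post.retweets,
        hashtag_tweets=pre.hashtag_tweets + post.hashtag_tweets,
        gps_tweets=pre.gps_tweets + post.gps_tweets,
    )


def hourly_series(
    records: Sequence[TweetRecord], spec: EventWindowSpec, metric: str = "tweets"
) -> HourlySeries:
    """Per-hour counts of a metric across the full analysis span.

    The hour bin of a record is ``floor((timestamp - event)/1h)``; bins run
    from ``-pre_start_offset_h`` up to (excluding) ``post_end_offset_h``.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    lo = math.floor(-spec.pre_start_offset_h)
    hi = math.ceil(spec.post_end_offset_h)
    offsets = tuple(range(lo, hi))
    counts = [0] * len(offsets)
    for rec in records:
        if metric == "retweets" and not rec.is_retweet:
            continue
        if metric == "hashtag_tweets" and not rec.hashtags:
            continue
        h = math.floor((rec.timestamp - spec.event_time) / timedelta(hours=1))
        if lo <= h < hi:
            counts[h - lo] += 1
    return HourlySeries(metric=metric, hour_offsets=offsets, counts=tuple(counts))


def fold_change(pre_value: float, post_value: float) -> float:
    """Post/pre ratio; undefined (error) when the pre value is zero."""
    if pre_value <= 0:
        raise ValueError("fold change undefined for nonpositive pre value")
    return post_value / pre_value
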