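"""Regional-user triangulation over three evidence channels.

A user is declared regional when any configured criterion row fires over the
observation span: a tweet mentioning a regional news outlet's handle, a
regional term in the profile biography, or a regional term / ZIP code in the
free-text location field.  Per-row accounting distinguishes *exclusive*
matches (the row was the only one to fire for that user) from *inclusive*
ones (at least one other row also fired) -- the measure of how much each
filter uniquely contributes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from tweetregion import defaults
from tweetregion.ingest import TweetRecord
from tweetregion.textmatch import any_term_matches, tokenize

CATEGORIES = ("tweet", "biography", "location")


@dataclass(frozen=True)
class RegionalCriterion:
    """One criterion row: a category, a label, and the terms it scans for.

    ``category`` selects the field inspected: ``tweet`` rows scan the user's
    mention set (including retweeted handles) for news handles, ``biography``
    rows scan the bio text, ``location`` rows the location string.  A
    ``location`` row may instead carry ``zip_ranges`` -- inclusive 5-digit
    ranges matched against any 5-digit token in the location.
    """

    category: str
    row_label: str
    terms: frozenset[str] = frozenset()
    zip_ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if not self.terms and not self.zip_ranges:
            raise ValueError("criterion row needs terms or zip ranges")
        object.__setattr__(self, "terms", frozenset(t.lower() for t in self.terms))


@dataclass(frozen=True)
class RegionalAssignment:
    """Per-user triangulation verdict with per-row exclusivity."""

    user_id: str
    matched_rows: frozenset[str]
    is_regional: bool
    exclusivity: Mapping[str, str]  # row_label -> "exclusive" | "inclusive"

    def __post_init__(self):
        if self.is_regional != bool(self.matched_rows):
            raise ValueError("is_regional must mirror matched_rows non-emptiness")


@dataclass
class CriterionCounts:
    """Per-row inclusive/exclusive user tallies plus the row->category map."""

    rows: dict[str, dict]  # row_label -> {category, inclusive_users, exclusive_users}
    total_regional: int


def default_criteria(
    news_handles: Iterable[str] = defaults.DEFAULT_NEWS_HANDLES,
    zip_ranges: Sequence[tuple[int, int]] = defaults.DEFAULT_ZIP_RANGES,
) -> list[RegionalCriterion]:
    """The shipped two-state criterion rows (editable via config)."""
    return [
        RegionalCriterion("tweet", "news_mention", frozenset(news_handles)),
        RegionalCriterion(
            "biography", "bio_state_city", frozenset(defaults.STATE_CITY_TERMS)
        ),
        RegionalCriterion(
            "biography", "bio_university", frozenset(defaults.UNIVERSITY_TERMS)
        ),
        RegionalCriterion("biography", "bio_chant", frozenset(defaults.CHANT_TERMS)),
        RegionalCriterion(
            "location", "loc_state_city", frozenset(defaults.STATE_CITY_TERMS)
        ),
        RegionalCriterion(
            "location", "loc_abbrev", frozenset(defaults.STATE_ABBREV_TERMS)
        ),
        RegionalCriterion("location", "loc_zip", zip_ranges=tuple(zip_ranges)),
        RegionalCriterion(
            "location", "loc_university", frozenset(defaults.UNIVERSITY_TERMS)
        ),
        RegionalCriterion("location", "loc_chant", frozenset(defaults.CHANT_TERMS)),
    ]


def latest_record(user_records: Sequence[TweetRecord]) -> TweetRecord:
    """The user's most recent record in the span (profile fields are taken
    from it, since bios/locations may change mid-span)."""
    return max(user_records, key=lambda r: r.timestamp)


def _zip_match(location: str, zip_ranges) -> bool:
    for tok in tokenize(location):
        if len(tok) == 5 and tok.isdigit():
            z = int(tok)
            if any(lo <= z <= hi for lo, hi in zip_ranges):
                return True
    return False


def classify_user(
    user_records: Sequence[TweetRecord],
    criteria: Sequence[RegionalCriterion],
    *,
    substring: bool = False,
) -> RegionalAssignment:
    """Triangulate one user's regional status from all their span records."""
    if not user_records:
        raise ValueError("user_records must be nonempty")
    if not criteria:
        raise ValueError("criteria must be nonempty")
    ids = {r.user_id for r in user_records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple users: {sorted(ids)}")

    latest = latest_record(user_records)
    mentions: set[str] = set()
    for rec in user_records:
        mentions |= rec.mentions
        if rec.retweeted_user:
            mentions.add(rec.retweeted_user)

    matched: set[str] = set()
    for crit in criteria:
        if crit.category == "tweet":
            if mentions & crit.terms:
                matched.add(crit.row_label)
        elif crit.category == "biography":
            if latest.bio and any_term_matches(
                crit.terms, latest.bio, substring=substring
            ):
                matched.add(crit.row_label)
        else:  # location
            loc = latest.location_string
            if not loc:
                continue
            if crit.zip_ranges and _zip_match(loc, crit.zip_ranges):
                matched.add(crit.row_label)
            elif crit.terms and any_term_matches(crit.terms, loc, substring=substring):
                matched.add(crit.row_label)

    exclusivity = {
        row: ("exclusive" if len(matched) == 1 else "inclusive") for row in matched
    }
    return RegionalAssignment(
        user_id=latest.user_id,
        matched_rows=frozenset(matched),
        is_regional=bool(matched),
        exclusivity=exclusivity,
    )


def classify_users(
    records: Sequence[TweetRecord],
    criteria: Sequence[RegionalCriterion],
    *,
    substring: bool = False,
) -> list[RegionalAssignment]:
    """Group records by user and triangulate each; one assignment per user."""
    by_user: dict[str, list[TweetRecord]] = {}
    for rec in records:
        by_user.setdefault(rec.user_id, []).append(rec)
    return [
        classify_user(recs, criteria, substring=substring)
        for recs in by_user.values()
    ]


def criterion_counts(
    assignments: Sequence[RegionalAssignment],
    criteria: Sequence[RegionalCriterion],
) -> CriterionCounts:
    """Per-row exclusive/inclusive user counts over deduplicated assignments."""
    seen = {a.user_id for a in assignments}
    if len(seen) != len(assignments):
        raise ValueError("assignments must be deduplicated by user")
    rows = {
        c.row_label: {
            "category": c.category,
            "inclusive_users": 0,
            "exclusive_users": 0,
        }
        for c in criteria
    }
    total_regional = 0
    for a in assignments:
        if not a.is_regional:
            continue
        total_regional += 1
        for row in a.matched_rows:
            key = (
                "exclusive_users" if len(a.matched_rows) == 1 else "inclusive_users"
            )
            rows[row][key] += 1
    return CriterionCounts(rows=rows, total_regional=total_regional)


def exclusive_share(counts: CriterionCounts, total_regional: int | None = None) -> dict[str, float]:
    """Percent of regional users captured exclusively by each category.

    Exclusive users are disjoint across rows (a user exclusive to a row
    matched no other row), so the per-category sum needs no deduplication.
    """
    total = counts.total_regional if total_regional is None else total_regional
    if total <= 0:
        raise ValueError("total_regional must be positive")
    shares = {cat: 0.0 for cat in CATEGORIES}
    for row in counts.rows.values():
        shares[row["category"]] += row["exclusive_users"]
    return {cat: 100.0 * n / total for cat, n in shares.items()}


def timezone_table(
    assignments: Sequence[RegionalAssignment],
    records: Sequence[TweetRecord],
) -> dict[str | None, int]:
    """User counts per profile time-zone string over the regional users.

    The zone is read from each user's most recent record; users with no zone
    fall in the ``None`` bucket.  Counts sum to the regional-user total.
    """
    regional = {a.user_id for a in assignments if a.is_regional}
    by_user: dict[str, list[TweetRecord]] = {}
    for rec in records:
        if rec.user_id in regional:
            by_user.setdefault(rec.user_id, []).append(rec)
    table: Counter[str | None] = Counter()
    for recs in by_user.values():
        table[latest_record(recs).time_zone] += 1
    return dict(table)
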