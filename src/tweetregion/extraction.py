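"""Broad first-pass rule extraction and the homonym purge.

Emulates commercial firehose filtering: a record enters the corpus when any
rule category fires -- disaster keywords in the text, disaster hashtags,
regional terms in the biography/location, a mention of a regional news
outlet, or a geotag inside the statewide region.  A separate purge drops homonym captures (the classic
failure: a substring filter for Petal, Mississippi sweeping in Petaling,
Malaysia).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from tweetregion.ingest import TweetRecord
from tweetregion.textmatch import matching_terms, tokenize

RULE_CATEGORIES = ("keyword", "hashtag", "bio_location", "news", "gps")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RuleSet:
    """Compiled first-pass extraction rules (all terms lowercased)."""

    keyword_terms: frozenset[str] = frozenset()
    hashtag_terms: frozenset[str] = frozenset()
    bio_location_terms: frozenset[str] = frozenset()
    news_handles: frozenset[str] = frozenset()
    gps_region: str | None = None

    def __post_init__(self):
        if not (
            self.keyword_terms
            or self.hashtag_terms
            or self.bio_location_terms
            or self.news_handles
            or self.gps_region
        ):
            raise ConfigurationError("rule set has no populated category")


@dataclass
class ExtractionResult:
    """Matched records, their fired rule categories/terms, and the purge tally."""

    matched: list[TweetRecord]
    rule_tags: list[frozenset[str]]
    matched_terms: list[frozenset[str]]
    purged_count: int = 0

    def __post_init__(self):
        if not (len(self.matched) == len(self.rule_tags) == len(self.matched_terms)):
            raise ValueError("parallel lists must have equal length")
        if any(not tags for tags in self.rule_tags):
            raise ValueError("every matched record needs at least one rule tag")
        if self.purged_count < 0:
            raise ValueError("purged_count must be nonnegative")


def _norm_terms(terms: Iterable[str], strip: str = "") -> frozenset[str]:
    out = set()
    for t in terms:
        t = str(t).strip().lstrip(strip).lower()
        if t:
            out.add(t)
    return frozenset(out)


def compile_ruleset(config: Mapping) -> RuleSet:
    """Compile a term-list config into a :class:`RuleSet`.

    Recognised keys: ``keywords``, ``hashtags`` (``#`` prefixes stripped),
    ``bio_location_terms``, ``news_handles`` (``@`` stripped), ``gps_region``.
    Terms are trimmed, lowercased, and deduplicated.
    """
    rs = RuleSet(
        keyword_terms=_norm_terms(config.get("keywords", ())),
        hashtag_terms=_norm_terms(config.get("hashtags", ()), strip="#"),
        bio_location_terms=_norm_terms(config.get("bio_location_terms", ())),
        news_handles=_norm_terms(config.get("news_handles", ()), strip="@"),
        gps_region=config.get("gps_region") or None,
    )
    return rs


def apply_ruleset(
    records: Sequence[TweetRecord],
    ruleset: RuleSet,
    polygons: Mapping | None = None,
    *,
    substring: bool = False,
) -> ExtractionResult:
    """Match records against the rule set; every fired category is tagged.

    ``polygons`` maps region ids to shapely geometries and is required when
    ``ruleset.gps_region`` is set.  ``substring=True`` switches term matching
    from word-boundary tokens to naive substring containment (the
    compatibility mode that reproduces homonym capture).
    """
    from tweetregion.validation import point_in_region

    if ruleset.gps_region and polygons is None:
        raise ConfigurationError("gps_region set but no polygons supplied")

    matched: list[TweetRecord] = []
    tags_out: list[frozenset[str]] = []
    terms_out: list[frozenset[str]] = []
    for rec in records:
        tags: set[str] = set()
        terms: set[str] = set()
        kw = matching_terms(ruleset.keyword_terms, rec.text, substring=substring)
        if kw:
            tags.add("keyword")
            terms |= kw
        ht = ruleset.hashtag_terms & rec.hashtags
        if ht:
            tags.add("hashtag")
            terms |= ht
        for text in (rec.bio, rec.location_string):
            if text:
                bl = matching_terms(
                    ruleset.bio_location_terms, text, substring=substring
                )
                if bl:
                    tags.add("bio_location")
                    terms |= bl
        if ruleset.news_handles:
            handles = set(rec.mentions)
            if rec.retweeted_user:
                handles.add(rec.retweeted_user)
            if handles & ruleset.news_handles:
                tags.add("news")
        if ruleset.gps_region and rec.geo is not None:
            lat, lon = rec.geo
            if point_in_region(lon, lat, polygons) is not None:
                tags.add("gps")
        if tags:
            matched.append(rec)
            tags_out.append(frozenset(tags))
            terms_out.append(frozenset(terms))
    return ExtractionResult(matched, tags_out, terms_out)


def purge_homonyms(
    result: ExtractionResult,
    exclusions: Iterable[str],
    polygons: Mapping | None = None,
) -> ExtractionResult:
    """Drop homonym captures from an extraction result.

    A record is purged when (a) its location string contains an exclusion
    place name as a token, or (b) its geotag lies outside the supplied
    region envelope while every term that matched it is a strict prefix of
    an exclusion term (the substring-capture signature).  Idempotent; the
    purge count accumulates.
    """
    from tweetregion.validation import point_in_region

    exclusions = {str(e).lower() for e in exclusions}
    if not exclusions:
        return result

    keep_recs, keep_tags, keep_terms = [], [], []
    purged = 0
    for rec, tags, terms in zip(result.matched, result.rule_tags, result.matched_terms):
        drop = False
        if rec.location_string:
            toks = set(tokenize(rec.location_string))
            if toks & exclusions:
                drop = True
        if not drop and polygons is not None and rec.geo is not None and terms:
            lat, lon = rec.geo
            outside = point_in_region(lon, lat, polygons) is None
            prefix_only = all(
                any(exc.startswith(t) and exc != t for exc in exclusions)
                for t in terms
            )
            if outside and prefix_only:
                drop = True
        if drop:
            purged += 1
        else:
            keep_recs.append(rec)
            keep_tags.append(tags)
            keep_terms.append(terms)
    return ExtractionResult(
        keep_recs, keep_tags, keep_terms, result.purged_count + purged
    )
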