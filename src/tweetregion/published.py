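"""Reported reference values from the 2013 Hattiesburg EF-4 tornado analysis.

The original corpus is proprietary (commercial firehose data) and was never
deposited, so its per-row counts are not recomputable.  What *is*
recomputable is the printed arithmetic: the pre/post window columns combine
into the printed 96-hour totals, and the GPS-validation tallies combine into
the printed likely-regional count.  These fixtures encode the published
window summaries and validation tallies as inputs for those identity checks
and for worked examples.
"""

from __future__ import annotations

from tweetregion.analytics import WindowSummary

#: published pre-storm window column (48 h before impact, 2 h buffer shift)
REPORTED_PRE = WindowSummary(
    users=3_145,
    tweets=27_927,
    retweets=6_551,
    hashtag_tweets=5_763,
    gps_tweets=758,
    application_types=141,
    verified_users=3,
    languages=6,
    mean_account_length_days=785.0,
    mean_followers=745.0,
    mean_influence=33.0,
    mean_friends=506.0,
)

#: published post-storm window column
REPORTED_POST = WindowSummary(
    users=7_501,
    tweets=53_514,
    retweets=20_758,
    hashtag_tweets=13_598,
    gps_tweets=1_879,
    application_types=192,
    verified_users=3,
    languages=8,
    mean_account_length_days=846.0,
    mean_followers=779.0,
    mean_influence=34.0,
    mean_friends=504.0,
)

#: published GPS-validation tallies over the 96-hour regional users
REPORTED_GPS_VALIDATION = {
    "gps_users": 515,
    "gps_confirmed_users": 463,
    # 30 listed the impact city, 9 listed in-state locations
    "location_consistent_users": 39,
    "gps_tweets": 2_353,
    "gps_tweets_in_region": 2_290,
}
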