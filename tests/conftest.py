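from datetime import datetime, timedelta, timezone

import pytest

from tweetregion import defaults
from tweetregion.ingest import TweetRecord
from tweetregion.validation import load_region_polygons

EVENT = defaults.DEFAULT_EVENT_TIME


def make_record(
    tweet_id="t1",
    user_id="u1",
    timestamp=None,
    text="hello world",
    **kwargs,
):
    """Record factory with sane defaults for hand-built test corpora."""
    return TweetRecord(
        tweet_id=tweet_id,
        user_id=user_id,
        timestamp=timestamp or EVENT - timedelta(hours=1),
        text=text,
        **kwargs,
    )


@pytest.fixture(scope="session")
def region_polygons():
    return load_region_polygons(defaults.region_polygons_path())
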