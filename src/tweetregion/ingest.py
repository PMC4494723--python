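"""Normalization of raw JSON-lines activity records into tweet records.

One JSON object per line comes in (the reseller-style activity dialect); a
:class:`TweetRecord` per line comes out.  A tab-delimited flat-table
round-trip is provided because a flat table is the interchange format the
downstream filtration stages persist.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, fields
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

_HASHTAG_RE = re.compile(r"#(\w+)")
_MENTION_RE = re.compile(r"@(\w+)")
# pseudo-retweet prefix: "RT @handle: ..." or "RT @handle ..."
_RT_PREFIX_RE = re.compile(r"^\s*RT\s+@(\w+)\b[:\s]?", re.IGNORECASE)


class IngestError(ValueError):
    """A malformed activity line, annotated with its 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One normalized tweet with the user metadata the filters consume.

    ``geo`` is a ``(latitude, longitude)`` pair in WGS84 degrees when the user
    shared their position.  ``influence_score`` is a third-party per-user
    influence metric consumed as opaque metadata.
    """

    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str
    hashtags: frozenset[str] = frozenset()
    mentions: frozenset[str] = frozenset()
    is_retweet: bool = False
    retweeted_user: str | None = None
    bio: str | None = None
    location_string: str | None = None
    time_zone: str | None = None
    geo: tuple[float, float] | None = None
    source_app: str | None = None
    language: str | None = None
    verified: bool = False
    followers: int = 0
    friends: int = 0
    account_created: datetime | None = None
    influence_score: float | None = None

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")
        object.__setattr__(self, "timestamp", self.timestamp.astimezone(timezone.utc))
        if self.account_created is not None:
            if self.account_created.tzinfo is None:
                raise ValueError("account_created must be timezone-aware")
            object.__setattr__(
                self, "account_created", self.account_created.astimezone(timezone.utc)
            )
        if self.geo is not None:
            lat, lon = self.geo
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"geo out of range: {self.geo}")
            object.__setattr__(self, "geo", (float(lat), float(lon)))
        for name in ("hashtags", "mentions"):
            vals = getattr(self, name)
            if any(not t or any(ch.isspace() for ch in t) for t in vals):
                raise ValueError(f"{name} must be nonempty and whitespace-free")
            object.__setattr__(self, name, frozenset(v.lower() for v in vals))
        if self.followers < 0 or self.friends < 0:
            raise ValueError("followers/friends must be nonnegative")


#: source-field -> TweetRecord-field mapping for the shipped JSON-lines dialect
DEFAULT_DIALECT: dict[str, str] = {
    "id": "tweet_id",
    "user_id": "user_id",
    "created_at": "timestamp",
    "text": "text",
    "hashtags": "hashtags",
    "mentions": "mentions",
    "is_retweet": "is_retweet",
    "retweeted_user": "retweeted_user",
    "bio": "bio",
    "location": "location_string",
    "time_zone": "time_zone",
    "lat": "lat",
    "lon": "lon",
    "source": "source_app",
    "lang": "language",
    "verified": "verified",
    "followers": "followers",
    "friends": "friends",
    "account_created": "account_created",
    "influence": "influence_score",
}


def _parse_instant(value) -> datetime:
    if isinstance(value, (int, float)):
        return datetime.fromtimestamp(value, tz=timezone.utc)
    dt = datetime.fromisoformat(str(value))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def record_from_mapping(
    raw: dict,
    dialect: dict[str, str] | None = None,
    *,
    rt_heuristic: bool = False,
) -> TweetRecord:
    """Build a :class:`TweetRecord` from one parsed JSON object.

    Hashtags and mentions prefer structured fields; when absent they are
    extracted from the text by a ``#``/``@`` word-boundary token scan.  The
    native retweet flag is authoritative; the opt-in ``rt_heuristic`` also
    marks "RT @handle" text prefixes as retweets (pseudo-retweets).
    """
    dialect = DEFAULT_DIALECT if dialect is None else dialect
    mapped: dict[str, object] = {}
    for src, dst in dialect.items():
        if src in raw and raw[src] is not None:
            mapped[dst] = raw[src]

    for required in ("tweet_id", "user_id", "timestamp", "text"):
        if required not in mapped:
            raise ValueError(f"missing required field {required!r}")

    text = str(mapped["text"])
    kwargs: dict[str, object] = {
        "tweet_id": str(mapped["tweet_id"]),
        "user_id": str(mapped["user_id"]),
        "timestamp": _parse_instant(mapped["timestamp"]),
        "text": text,
    }

    if "hashtags" in mapped:
        kwargs["hashtags"] = frozenset(
            str(h).lstrip("#").lower() for h in mapped["hashtags"]
        )
    else:
        kwargs["hashtags"] = frozenset(m.lower() for m in _HASHTAG_RE.findall(text))
    if "mentions" in mapped:
        kwargs["mentions"] = frozenset(
            str(m).lstrip("@").lower() for m in mapped["mentions"]
        )
    else:
        kwargs["mentions"] = frozenset(m.lower() for m in _MENTION_RE.findall(text))

    if "is_retweet" in mapped:
        kwargs["is_retweet"] = bool(mapped["is_retweet"])
    if "retweeted_user" in mapped:
        kwargs["retweeted_user"] = str(mapped["retweeted_user"]).lstrip("@").lower()
    if rt_heuristic and not kwargs.get("is_retweet"):
        m = _RT_PREFIX_RE.match(text)
        if m:
            kwargs["is_retweet"] = True
            kwargs.setdefault("retweeted_user", m.group(1).lower())

    if "lat" in mapped and "lon" in mapped:
        kwargs["geo"] = (float(mapped["lat"]), float(mapped["lon"]))
    for opt in ("bio", "location_string", "time_zone", "source_app", "language"):
        if opt in mapped:
            kwargs[opt] = str(mapped[opt])
    if "verified" in mapped:
        kwargs["verified"] = bool(mapped["verified"])
    for num in ("followers", "friends"):
        if num in mapped:
            kwargs[num] = int(mapped[num])
    if "account_created" in mapped:
        kwargs["account_created"] = _parse_instant(mapped["account_created"])
    if "influence_score" in mapped:
        kwargs["influence_score"] = float(mapped["influence_score"])
    return TweetRecord(**kwargs)


def read_activity_stream(
    source: str | Path | TextIO | Iterable[str],
    dialect: dict[str, str] | None = None,
    *,
    rt_heuristic: bool = False,
    errors: str = "raise",
    error_log: list | None = None,
) -> list[TweetRecord]:
    """Read a JSON-lines activity stream into normalized tweet records.

    Parameters
    ----------
    source:
        Path, open text handle, or iterable of lines.
    dialect:
        Source-field to record-field mapping; defaults to the shipped dialect.
    errors:
        ``"raise"`` fails fast with the offending line number; ``"skip"``
        drops malformed lines, logs them, and (optionally) appends
        ``(lineno, message)`` pairs to ``error_log``.
    """
    if errors not in ("raise", "skip"):
        raise ValueError("errors must be 'raise' or 'skip'")

    close = False
    if isinstance(source, (str, Path)):
        handle: Iterable[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    records: list[TweetRecord] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
                records.append(
                    record_from_mapping(raw, dialect, rt_heuristic=rt_heuristic)
                )
            except (ValueError, TypeError, KeyError) as exc:
                err = IngestError(lineno, str(exc))
                if errors == "raise":
                    raise err from exc
                logger.warning("skipping malformed record: %s", err)
                if error_log is not None:
                    error_log.append((lineno, str(exc)))
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return records


# --- flat-table round-trip --------------------------------------------------

FLAT_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(TweetRecord))

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r", "N": None}


def _escape(cell: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in cell)


def _unescape(cell: str) -> str | None:
    if cell == "\\N":
        return None
    out: list[str] = []
    it = iter(cell)
    for c in it:
        if c == "\\":
            nxt = next(it)
            if nxt == "N":
                raise ValueError("\\N is only valid as a whole cell")
            out.append(_UNESCAPES[nxt])
        else:
            out.append(c)
    return "".join(out)


def _cell(value) -> str:
    if value is None:
        return "\\N"
    if isinstance(value, frozenset):
        return ",".join(sorted(value))
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, tuple):  # geo
        return f"{value[0]!r},{value[1]!r}"
    if isinstance(value, bool):
        return "true" if value else "false"
    return _escape(str(value))


def write_flat_table(records: Sequence[TweetRecord], sink: str | Path | TextIO) -> int:
    """Write records as a UTF-8 tab-delimited table; returns rows written.

    Embedded tabs/newlines/backslashes are backslash-escaped and absent
    optional fields are encoded as ``\\N``, so the table reads back
    field-for-field identical.
    """
    close = False
    if isinstance(sink, (str, Path)):
        handle: TextIO = open(sink, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = sink
    try:
        handle.write("\t".join(FLAT_COLUMNS) + "\n")
        n = 0
        for rec in records:
            handle.write(
                "\t".join(_cell(getattr(rec, col)) for col in FLAT_COLUMNS) + "\n"
            )
            n += 1
        return n
    finally:
        if close:
            handle.close()


def _parse_cell(name: str, cell: str):
    value = _unescape(cell)
    if value is None:
        return None
    if name in ("hashtags", "mentions"):
        return frozenset(v for v in value.split(",") if v)
    if name in ("timestamp", "account_created"):
        return datetime.fromisoformat(value)
    if name == "geo":
        lat, lon = value.split(",")
        return (float(lat), float(lon))
    if name in ("is_retweet", "verified"):
        return value == "true"
    if name in ("followers", "friends"):
        return int(value)
    if name == "influence_score":
        return float(value)
    return value


def read_flat_table(source: str | Path | TextIO) -> list[TweetRecord]:
    """Read back a table written by :func:`write_flat_table`."""
    close = False
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    try:
        lines = handle.read().split("\n")
    finally:
        if close:
            handle.close()
    if not lines or lines[0].split("\t") != list(FLAT_COLUMNS):
        raise ValueError("missing or mismatched flat-table header")
    records = []
    for row in lines[1:]:
        if not row:
            continue
        cells = row.split("\t")
        if len(cells) != len(FLAT_COLUMNS):
            raise ValueError(f"expected {len(FLAT_COLUMNS)} cells, got {len(cells)}")
        kwargs = {
            name: _parse_cell(name, cell) for name, cell in zip(FLAT_COLUMNS, cells)
        }
        records.append(TweetRecord(**kwargs))
    return records
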