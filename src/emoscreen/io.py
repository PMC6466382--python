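"""File formats: JSONL tweet streams, CSV profiles/labels/results.

Tweets are JSONL records {"user_id", "timestamp", "text"} with ISO-8601
timestamps.  Per-user accumulation keeps each user's tweets inside an
observation window (default 14 days from their earliest tweet), matching
the two-week collection period the screening model assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnosis import ConditionProfile, DiagnosisResult
from .lexicon import CATEGORIES_11
from .training import LabeledUser

DEFAULT_WINDOW_DAYS = 14


@dataclass(frozen=True)
class Tweet:
    user_id: str
    timestamp: datetime
    text: str


def read_tweets_jsonl(path: str | Path) -> list[Tweet]:
    tweets = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            tweets.append(
                Tweet(
                    user_id=str(rec["user_id"]),
                    timestamp=datetime.fromisoformat(rec["timestamp"]),
                    text=str(rec["text"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad tweet record ({exc})") from exc
    return tweets


def write_tweets_jsonl(tweets: Iterable[Tweet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "user_id": t.user_id,
                        "timestamp": t.timestamp.isoformat(),
                        "text": t.text,
                    }
                )
                + "\n"
            )


def user_texts(
    tweets: Sequence[Tweet], window_days: int = DEFAULT_WINDOW_DAYS
) -> dict[str, list[str]]:
    """Group tweets by user, keeping each user's tweets within
    ``window_days`` of their earliest tweet (chronological order)."""
    by_user: dict[str, list[Tweet]] = {}
    for t in tweets:
        by_user.setdefault(t.user_id, []).append(t)
    out: dict[str, list[str]] = {}
    for uid, ts in by_user.items():
        ts.sort(key=lambda t: t.timestamp)
        horizon = ts[0].timestamp + timedelta(days=window_days)
        out[uid] = [t.text for t in ts if t.timestamp <= horizon]
    return out


def cohort_to_tweets(
    cohort: Iterable[LabeledUser], start: datetime | None = None
) -> list[Tweet]:
    """Lay a synthetic cohort's texts onto an hourly timeline."""
    start = start or datetime(2018, 7, 1)
    tweets = []
    for user in cohort:
        for i, text in enumerate(user.texts):
            tweets.append(Tweet(user.user_id, start + timedelta(hours=i * 6), text))
    return tweets


# ---------------------------------------------------------------------------
# CSV formats


def write_profiles_csv(profiles: Iterable[ConditionProfile], path: str | Path) -> None:
    rows = [
        {"condition": p.condition, **{c: p.vector[i] for i, c in enumerate(CATEGORIES_11)}}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[ConditionProfile]:
    df = pd.read_csv(path)
    missing = set(CATEGORIES_11) - set(df.columns)
    if missing:
        raise ValueError(f"profile file missing sentiment columns: {sorted(missing)}")
    return [
        ConditionProfile(row["condition"], np.array([row[c] for c in CATEGORIES_11]))
        for _, row in df.iterrows()
    ]


def write_labels_csv(cohort: Iterable[LabeledUser], path: str | Path) -> None:
    rows = [
        {"user_id": u.user_id, "conditions": ";".join(sorted(u.conditions))}
        for u in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, dtype={"user_id": str}, keep_default_na=False)
    return {
        row["user_id"]: set(filter(None, str(row["conditions"]).split(";")))
        for _, row in df.iterrows()
    }


def write_distributions_csv(
    dists: Mapping[str, "np.ndarray"], path: str | Path
) -> None:
    rows = [
        {"user_id": uid, **{c: float(v[i]) for i, c in enumerate(CATEGORIES_11)}}
        for uid, v in dists.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_csv(results: Iterable[DiagnosisResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row: dict = {"user_id": r.user_id, "insufficient_evidence": r.insufficient_evidence}
        for cond, prob in r.probs.items():
            row[f"prob_{cond}"] = prob
            row[f"level_{cond}"] = r.levels[cond].value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
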