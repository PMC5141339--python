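"""Story-signal trend statistics.

Monthly keyword-prevalence series over a forum corpus: the proportion of
new posts containing a keyword, the proportion of each month's new users
who committed such a post within that joining month, and the cumulative
proportion of keyword posts — plus the distribution of user-activity
duration in days (last post minus first post), binned at three months.

"Containing the keyword" means a case-insensitive standalone-token match;
``token+plural`` mode additionally folds the bare plural (keyword + "s").
All months are UTC calendar months; months with zero posts are emitted
with their proportions recorded as missing, never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._text import tokenize
from .corpus import Corpus

logger = logging.getLogger(__name__)


class TrendsError(ValueError):
    pass


def keyword_predicate(text: str, keyword: str, mode: str = "token") -> bool:
    """True when the keyword occurs as a standalone token in the text.

    ``mode='token+plural'`` also accepts the keyword followed by "s".
    """
    if not keyword:
        raise TrendsError("keyword must be nonempty")
    if mode not in ("token", "token+plural"):
        raise TrendsError(f"unknown keyword mode {mode!r}")
    targets = {keyword.lower()}
    if mode == "token+plural":
        targets.add(keyword.lower() + "s")
    return any(tok.lower() in targets for tok in tokenize(text))


def monthly_signal(
    corpus: Corpus, keyword: str, mode: str = "token"
) -> pd.DataFrame:
    """Monthly keyword-signal statistics as a DataFrame.

    Columns: ``month`` (period), ``n_posts``, ``n_keyword_posts``,
    ``proportion`` (keyword share of the month's posts), ``n_new_users``,
    ``n_new_users_keyword``, ``proportion_new_users``, ``cum_posts``,
    ``cum_keyword_posts``, ``proportion_cumulative``.  A user is *new* in
    the calendar month of their first post and counts toward the keyword
    numerator when any of their posts in that month matches the predicate.
    """
    if not corpus.posts:
        raise TrendsError("corpus has no posts")
    frame = pd.DataFrame({
        "user_id": [p.user_id for p in corpus.posts],
        "timestamp": [p.timestamp for p in corpus.posts],
        "keyword": [keyword_predicate(p.text, keyword, mode)
                    for p in corpus.posts],
    })
    if frame["timestamp"].isna().any():
        raise TrendsError("corpus has missing timestamps")
    frame["month"] = frame["timestamp"].dt.to_period("M")

    months = pd.period_range(frame["month"].min(), frame["month"].max(), freq="M")
    by_month = frame.groupby("month").agg(
        n_posts=("keyword", "size"), n_keyword_posts=("keyword", "sum")
    ).reindex(months, fill_value=0)

    first_month = frame.groupby("user_id")["month"].min()
    frame = frame.merge(first_month.rename("first_month"), on="user_id")
    new_posts = frame[frame["month"] == frame["first_month"]]
    new_users = new_posts.groupby("month")["user_id"].nunique()
    new_users_kw = (
        new_posts[new_posts["keyword"]].groupby("month")["user_id"].nunique()
    )
    by_month["n_new_users"] = new_users.reindex(months, fill_value=0)
    by_month["n_new_users_keyword"] = new_users_kw.reindex(months, fill_value=0)

    by_month["proportion"] = np.where(
        by_month["n_posts"] > 0,
        by_month["n_keyword_posts"] / by_month["n_posts"].replace(0, np.nan),
        np.nan,
    )
    by_month["proportion_new_users"] = (
        by_month["n_new_users_keyword"]
        / by_month["n_new_users"].replace(0, np.nan)
    )
    by_month["cum_posts"] = by_month["n_posts"].cumsum()
    by_month["cum_keyword_posts"] = by_month["n_keyword_posts"].cumsum()
    by_month["proportion_cumulative"] = (
        by_month["cum_keyword_posts"]
        / by_month["cum_posts"].replace(0, np.nan)
    )
    by_month = by_month.reset_index(names="month")
    return by_month[[
        "month", "n_posts", "n_keyword_posts", "proportion",
        "n_new_users", "n_new_users_keyword", "proportion_new_users",
        "cum_posts", "cum_keyword_posts", "proportion_cumulative",
    ]]


@dataclass
class DurationHistogram:
    """User-activity-duration histogram with half-open day bins."""

    bin_edges: np.ndarray  # length n_bins + 1, in days
    counts: np.ndarray  # integer user counts per bin

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def log_counts(self) -> np.ndarray:
        """Natural log of counts (log of zero counts is -inf)."""
        with np.errstate(divide="ignore"):
            return np.log(self.counts.astype(float))

    def fitted_slope(self, min_count: int = 5) -> float:
        """Least-squares slope of log-counts vs bin midpoint (per day),
        over bins with at least ``min_count`` users."""
        mask = self.counts >= min_count
        if mask.sum() < 2:
            raise TrendsError("too few populated bins to fit a slope")
        slope, _ = np.polyfit(self.midpoints[mask],
                              np.log(self.counts[mask].astype(float)), 1)
        return float(slope)


def activity_duration_histogram(
    corpus: Corpus, bin_width_days: int = 90
) -> DurationHistogram:
    """Distribution of per-user activity duration in days.

    Duration = last post date minus first post date; single-post users
    have duration 0 and fall in the first bin.  Bins are half-open
    ``[lo, hi)`` of width ``bin_width_days`` (90 days = 3 months).
    """
    if not corpus.posts:
        raise TrendsError("corpus has no posts")
    frame = pd.DataFrame({
        "user_id": [p.user_id for p in corpus.posts],
        "date": [p.timestamp.normalize() for p in corpus.posts],
    })
    span = frame.groupby("user_id")["date"].agg(["min", "max"])
    durations = (span["max"] - span["min"]).dt.days.to_numpy()
    n_bins = int(durations.max() // bin_width_days) + 1 if len(durations) else 1
    edges = np.arange(0, (n_bins + 1) * bin_width_days, bin_width_days)
    counts, _ = np.histogram(durations, bins=edges)
    return DurationHistogram(bin_edges=edges, counts=counts)


def write_signal_csv(signal: pd.DataFrame, path: str | Path,
                     site_id: str = "") -> Path:
    out = signal.copy()
    out.insert(0, "site_id", site_id)
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)
    return Path(path)


def write_histogram_csv(hist: DurationHistogram, path: str | Path) -> Path:
    frame = pd.DataFrame({
        "bin_lo_days": hist.bin_edges[:-1],
        "bin_hi_days": hist.bin_edges[1:],
        "count": hist.counts,
    })
    frame.to_csv(path, index=False)
    return Path(path)
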