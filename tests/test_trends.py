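"""Keyword trend series and activity-duration histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narraframe.corpus import Corpus
from narraframe.trends import (
    TrendsError,
    activity_duration_histogram,
    keyword_predicate,
    monthly_signal,
)

from conftest import make_post


@pytest.mark.parametrize("text,keyword,mode,expected", [
    ("Religious Exemption info", "exemption", "token", True),
    ("exemptions", "exemption", "token", False),
    ("exemptions", "exemption", "token+plural", True),
    ("tax-exempt", "exemption", "token", False),
    ("tax-exempt", "exemption", "token+plural", False),
    ("EXEMPTION!", "exemption", "token", True),
    ("no match here", "exemption", "token", False),
])
def test_keyword_predicate(text, keyword, mode, expected):
    assert keyword_predicate(text, keyword, mode) is expected


def test_keyword_predicate_rejects_bad_input():
    with pytest.raises(TrendsError):
        keyword_predicate("x", "")
    with pytest.raises(TrendsError):
        keyword_predicate("x", "y", mode="regex")


def _post(i, user, ts, kw=False):
    return make_post(post_id=f"p{i}", user=user, ts=ts,
                     text="exemption talk" if kw else "other talk")


def test_monthly_signal_hand_count():
    posts = (
        [_post(i, f"u{i}", "2008-01-10", kw=(i < 2)) for i in range(10)]
        + [_post(10 + i, f"v{i}", "2008-02-05") for i in range(5)]
    )
    signal = monthly_signal(Corpus(posts=posts), "exemption")
    assert list(signal["proportion"]) == pytest.approx([0.2, 0.0])
    assert signal["proportion_cumulative"].iloc[-1] == pytest.approx(2 / 15)
    # all 15 users are new in their posting month
    assert list(signal["n_new_users"]) == [10, 5]
    assert list(signal["n_new_users_keyword"]) == [2, 0]


def test_monthly_signal_single_keyword_post():
    signal = monthly_signal(
        Corpus(posts=[_post(0, "u", "2008-03-03", kw=True)]), "exemption")
    assert signal["proportion"].iloc[0] == 1.0
    assert signal["proportion_new_users"].iloc[0] == 1.0
    assert signal["proportion_cumulative"].iloc[0] == 1.0


def test_empty_months_recorded_as_missing_not_zero():
    posts = [_post(0, "u", "2008-01-10", kw=True),
             _post(1, "u", "2008-03-10")]
    signal = monthly_signal(Corpus(posts=posts), "exemption")
    assert len(signal) == 3
    feb = signal.iloc[1]
    assert feb["n_posts"] == 0
    assert np.isnan(feb["proportion"])
    assert np.isnan(feb["proportion_new_users"])
    # cumulative carries forward over the gap
    assert feb["proportion_cumulative"] == 1.0


def test_new_user_counted_in_keyword_numerator_only_for_joining_month():
    posts = [_post(0, "u", "2008-01-10"),  # u joins in Jan without keyword
             _post(1, "u", "2008-02-10", kw=True)]  # keyword later
    signal = monthly_signal(Corpus(posts=posts), "exemption")
    assert list(signal["n_new_users_keyword"]) == [0, 0]
    assert list(signal["n_new_users"]) == [1, 0]


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 5), st.integers(0, 400), st.booleans()),
    min_size=1, max_size=40,
))
def test_signal_identities(events):
    """Cumulative identity holds exactly, every user is new exactly once,
    and invariant bounds hold."""
    posts = [
        make_post(post_id=f"p{i}", user=f"u{uid}",
                  ts=pd.Timestamp("2008-01-01") + pd.Timedelta(days=day),
                  text="exemption" if kw else "nothing")
        for i, (uid, day, kw) in enumerate(events)
    ]
    signal = monthly_signal(Corpus(posts=posts), "exemption")
    assert signal["n_new_users"].sum() == len({p.user_id for p in posts})
    assert (signal["n_new_users_keyword"] <= signal["n_new_users"]).all()
    assert signal["cum_posts"].is_monotonic_increasing
    expected_cum = signal["n_keyword_posts"].cumsum() / signal["n_posts"].cumsum()
    both = signal["proportion_cumulative"].to_numpy()
    assert np.allclose(both, expected_cum.to_numpy(), equal_nan=True, atol=0)
    props = signal[["proportion", "proportion_new_users",
                    "proportion_cumulative"]].to_numpy()
    finite = props[~np.isnan(props)]
    assert ((finite >= 0) & (finite <= 1)).all()


def test_duration_binning_examples():
    posts = [
        make_post(post_id="p1", user="u1", ts="2008-01-01"),
        make_post(post_id="p2", user="u1", ts="2008-04-10"),  # day 100
        make_post(post_id="p3", user="u2", ts="2008-02-01"),  # single post
    ]
    hist = activity_duration_histogram(Corpus(posts=posts))
    assert hist.bin_edges[0] == 0 and hist.bin_edges[1] == 90
    assert hist.counts[0] == 1  # single-post user at duration 0
    assert hist.counts[1] == 1  # duration 100 in [90, 180)
    assert hist.counts.sum() == 2


def test_all_single_post_users_mass_in_first_bin():
    posts = [make_post(post_id=f"p{i}", user=f"u{i}", ts="2008-01-05")
             for i in range(7)]
    hist = activity_duration_histogram(Corpus(posts=posts))
    assert hist.counts[0] == 7
    assert hist.counts.sum() == 7
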