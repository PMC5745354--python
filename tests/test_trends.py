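"""Monthly panel construction, rankings, correlations, trajectories."""

from datetime import datetime, timezone

import numpy as np
import pytest
from scipy import stats

from lynchtweets.trends import (
    CorrelationResult,
    build_panel,
    correlation_table,
    format_p,
    pearson_correlation,
    sentiment_trajectory,
    topic_proportions,
    topic_volume_ranking,
)


def _ts(month: str, day: int = 15) -> datetime:
    return datetime(int(month[:4]), int(month[5:7]), day, tzinfo=timezone.utc)


def _tweet(month, label, topic=None, sentiment=None):
    return {
        "timestamp": _ts(month), "label": label,
        "topic": topic, "sentiment": sentiment,
    }


class TestBuildPanel:
    def test_empty_input(self):
        panel = build_panel([])
        assert panel.empty

    def test_one_tweet_per_class_sums_to_three(self):
        rows = [
            _tweet("2017-03", "irrelevant"),
            _tweet("2017-03", "promotional", topic="risk"),
            _tweet("2017-03", "layperson", topic="risk", sentiment="positive"),
        ]
        panel = build_panel(rows)
        assert panel["count"].sum() == 3
        assert set(panel["month"]) == {"2017-03"}

    def test_counts_conserved_and_no_polarity_outside_layperson(self):
        rows = [
            _tweet("2017-01", "promotional", topic="a", sentiment="positive"),
            _tweet("2017-02", "layperson", topic="a", sentiment="negative"),
            _tweet("2017-02", "layperson", topic=None, sentiment="neutral"),
        ]
        panel = build_panel(rows)
        assert panel["count"].sum() == len(rows)
        promo = panel[panel["class"] == "promotional"]
        assert (promo["polarity"] == "").all()
        assert (panel[panel["topic"] == "none"]["count"] == 1).all()

    def test_out_of_range_months_excluded_with_warning(self):
        rows = [_tweet("2016-09", "layperson"), _tweet("2017-01", "layperson")]
        with pytest.warns(UserWarning):
            panel = build_panel(rows, months=["2017-01"])
        assert panel["count"].sum() == 1


class TestRankingAndProportions:
    def test_ranking_with_tie_break(self):
        rows = (
            [_tweet("2017-01", "promotional", topic="b")] * 10
            + [_tweet("2017-01", "promotional", topic="a")] * 10
            + [_tweet("2017-01", "promotional", topic="c")] * 5
        )
        ranking = topic_volume_ranking(build_panel(rows))
        assert ranking == [("a", 10), ("b", 10), ("c", 5)]

    def test_ranking_empty_panel_errors(self):
        with pytest.raises(ValueError):
            topic_volume_ranking(build_panel([]))

    def test_proportions_sum_to_one_and_exclude_none(self):
        rows = (
            [_tweet("2017-01", "layperson", topic="a")] * 3
            + [_tweet("2017-01", "layperson", topic="b")]
            + [_tweet("2017-01", "layperson", topic=None)]
        )
        props = topic_proportions(build_panel(rows), "layperson")
        assert props == {"a": 0.75, "b": 0.25}
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_proportions_empty_class_errors(self):
        rows = [_tweet("2017-01", "layperson", topic="a")]
        with pytest.raises(ValueError):
            topic_proportions(build_panel(rows), "promotional")


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_correlation([1, 2, 3], [3, 5, 7])
        assert r == pytest.approx(1.0, abs=1e-12) and p < 1e-6
        r, _ = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_value(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_constant_series_missing(self):
        assert pearson_correlation([1, 1, 1], [1, 2, 3]) == (None, None)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_correlation(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r, _ = pearson_correlation(x, y)
            num = sum(
                (a - np.mean(x)) * (b - np.mean(y)) for a, b in zip(x, y)
            )
            den = np.sqrt(
                sum((a - np.mean(x)) ** 2 for a in x)
                * sum((b - np.mean(y)) ** 2 for b in y)
            )
            assert r == pytest.approx(num / den, abs=1e-12)


class TestCorrelationTable:
    @staticmethod
    def _coupled_panel():
        rows = []
        months = [f"2017-{m:02d}" for m in range(1, 10)]
        promo = [10, 20, 60, 30, 15, 10, 8, 12, 25]
        for month, n in zip(months, promo):
            rows += [_tweet(month, "promotional", topic="awareness")] * n
            rows += [_tweet(month, "layperson", topic="awareness",
                            sentiment="neutral")] * (2 * n)
        return build_panel(rows)

    def test_proportional_series_give_r_one(self):
        (result,) = correlation_table(self._coupled_panel())
        assert isinstance(result, CorrelationResult)
        assert result.r == pytest.approx(1.0, abs=1e-12)
        assert result.p < 1e-12
        assert result.n == 9

    def test_symmetric_under_class_swap(self):
        panel = self._coupled_panel()
        swapped = panel.copy()
        swapped["class"] = swapped["class"].map(
            {"promotional": "layperson", "layperson": "promotional"}
        )
        swapped["polarity"] = ""
        (a,) = correlation_table(panel)
        (b,) = correlation_table(swapped)
        assert a.r == pytest.approx(b.r)

    def test_requires_three_months(self):
        rows = [_tweet("2017-01", "layperson", topic="a"),
                _tweet("2017-02", "layperson", topic="a")]
        with pytest.raises(ValueError):
            correlation_table(build_panel(rows))

    def test_null_calibration(self):
        """|r| of independent series exceeds the 5% critical value ~5% of
        the time (Monte-Carlo on 12-month Poisson pairs)."""
        rng = np.random.default_rng(101)
        crit = 0.576  # two-sided 5% point for n=12
        exceed = sum(
            abs(pearson_correlation(
                rng.poisson(20, size=12), rng.poisson(20, size=12)
            )[0]) > crit
            for _ in range(1000)
        )
        assert 20 <= exceed <= 90  # nominal 50 of 1000


class TestTrajectory:
    def test_all_neutral_months_are_zero(self):
        rows = [
            _tweet("2017-01", "layperson", topic="a", sentiment="neutral"),
            _tweet("2017-02", "layperson", topic="a", sentiment="neutral"),
        ]
        traj = sentiment_trajectory(build_panel(rows), "a")
        assert (traj == 0.0).all()

    def test_hand_value_and_missing_month(self):
        rows = (
            [_tweet("2017-01", "layperson", topic="a", sentiment="positive")] * 2
            + [_tweet("2017-01", "layperson", topic="a", sentiment="negative")]
            + [_tweet("2017-01", "layperson", topic="a", sentiment="neutral")]
            + [_tweet("2017-02", "layperson", topic="b", sentiment="neutral")]
        )
        traj = sentiment_trajectory(build_panel(rows), "a")
        assert traj["2017-01"] == pytest.approx(0.25)
        assert np.isnan(traj["2017-02"])  # no topic-a tweets that month


def test_format_p():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.02) == "0.020"
    assert format_p(None) == "NA"
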