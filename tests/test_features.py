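import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarediary import (
    DailyEntry,
    ParticipantSeries,
    aggregate_flare_features,
    derive_flare_states,
    eligibility_filter,
    feature_frame,
    normalize_features,
)
from flarediary.features import FeatureRow

D0 = dt.date(2020, 1, 1)


def _series(day_scores: list[dict]) -> ParticipantSeries:
    entries = [
        DailyEntry("P1", D0 + dt.timedelta(days=t), scores)
        for t, scores in enumerate(day_scores)
    ]
    return ParticipantSeries("P1", entries)


def _aggregate(day_scores):
    s = _series(day_scores)
    return aggregate_flare_features(s, derive_flare_states(s))


class TestAggregate:
    def test_split_means_and_diff(self):
        row = _aggregate(
            [
                {"flare": 1, "pain": 2},
                {"flare": 2, "pain": 3},
                {"flare": 5, "pain": 4},
                {"flare": 4, "pain": 4},
            ]
        )
        assert row.mean_on["pain"] == pytest.approx(2.5)
        assert row.mean_off["pain"] == pytest.approx(4.0)
        assert row.diff("pain") == pytest.approx(-1.5)
        assert (row.n_on["pain"], row.n_off["pain"]) == (2, 2)

    def test_identical_scores_zero_diff(self):
        row = _aggregate([{"flare": 1, "pain": 3}, {"flare": 5, "pain": 3}])
        assert row.diff("pain") == pytest.approx(0.0)

    def test_one_sided_variable_has_no_diff(self):
        # pain never scored on a flare-on day
        row = _aggregate([{"flare": 1}, {"flare": 5, "pain": 4}])
        assert row.diff("pain") is None
        assert "pain" not in row.mean_on

    def test_undefined_flare_state_excluded(self):
        row = _aggregate(
            [
                {"pain": 1},  # no flare score: contributes nothing
                {"flare": 1, "pain": 2},
                {"flare": 5, "pain": 4},
            ]
        )
        assert row.mean_on["pain"] == pytest.approx(2.0)
        assert row.mean_off["pain"] == pytest.approx(4.0)

    def test_matches_one_pass_pandas_oracle(self):
        """mean_on/mean_off reproduce a groupby computed independently on
        the long table of a synthetic cohort."""
        from flarediary import generate_cohort, SyntheticCohortConfig
        from flarediary.io import series_to_frame

        series, _, _ = generate_cohort(
            SyntheticCohortConfig(n_participants=8, followup_mean_days=60.0), seed=3
        )
        for s in series:
            states = derive_flare_states(s, 3)
            row = aggregate_flare_features(s, states)
            frame = series_to_frame([s]).pivot(
                index="date", columns="variable", values="score"
            )
            on = frame["flare"] <= 3
            for v in frame.columns:
                if v == "flare":
                    continue
                for mask, means in ((on, row.mean_on), (~on & frame["flare"].notna(), row.mean_off)):
                    expected = frame.loc[mask, v].mean()
                    if pd.isna(expected):
                        assert v not in means
                    else:
                        assert means[v] == pytest.approx(expected)


class TestEligibility:
    def _rows(self, days):
        return [FeatureRow(f"P{i}", n_entry_days=d) for i, d in enumerate(days)]

    def test_min_days_boundary(self):
        kept = eligibility_filter(self._rows([9, 10, 11]), min_days=10)
        assert [r.n_entry_days for r in kept] == [10, 11]

    def test_zero_flare_participant_dropped_for_clustering(self):
        with_flare = FeatureRow(
            "A", {"pain": 2.0}, {"pain": 4.0}, {"pain": 3}, {"pain": 5}, 20
        )
        never_flared = FeatureRow("B", {}, {"pain": 4.0}, {}, {"pain": 20}, 20)
        kept = eligibility_filter(
            [with_flare, never_flared], 10, require_diff_variables=["pain"]
        )
        assert [r.participant_id for r in kept] == ["A"]
        # but both pass the plain adherence filter
        assert len(eligibility_filter([with_flare, never_flared], 10)) == 2

    @given(days=st.lists(st.integers(1, 40), max_size=20), cut=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_min_days(self, days, cut):
        rows = self._rows(days)
        low = {r.participant_id for r in eligibility_filter(rows, cut)}
        high = {r.participant_id for r in eligibility_filter(rows, cut + 1)}
        assert high <= low


class TestNormalize:
    def test_symmetric_minmax(self):
        m = pd.DataFrame({"a_diff": [-2.0, 0.0, 2.0]}, index=["x", "y", "z"])
        out = normalize_features(m)
        assert out.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert not out.degenerate[0]

    def test_asymmetric_column(self):
        m = pd.DataFrame({"a_diff": [-1.0, 0.0, 3.0]})
        out = normalize_features(m)
        assert out.values[:, 0] == pytest.approx([-1.0, -0.5, 1.0])

    def test_constant_column_degenerate(self):
        m = pd.DataFrame({"a_diff": [0.3, 0.3]})
        out = normalize_features(m)
        assert out.values[:, 0] == pytest.approx([0.0, 0.0])
        assert out.degenerate[0]

    def test_maxabs_preserves_sign(self):
        m = pd.DataFrame({"a_diff": [-1.0, 0.0, 3.0]})
        out = normalize_features(m, scheme="maxabs")
        assert out.values[:, 0] == pytest.approx([-1 / 3, 0.0, 1.0])

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a_diff": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="complete-case"):
            normalize_features(m)

    @given(
        values=st.lists(
            st.floats(-4, 4, allow_nan=False), min_size=3, max_size=10, unique=True
        ),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, values, scale, shift):
        """Min-max output is unchanged by affine transforms of the raw column."""
        raw = pd.DataFrame({"a_diff": values})
        transformed = pd.DataFrame({"a_diff": [scale * v + shift for v in values]})
        a = normalize_features(raw).values
        b = normalize_features(transformed).values
        assert a[:, 0] == pytest.approx(b[:, 0], abs=1e-9)

    def test_every_column_attains_extremes(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 4)), columns=[f"v{i}_diff" for i in range(4)])
        out = normalize_features(m)
        assert out.values.min(axis=0) == pytest.approx([-1.0] * 4)
        assert out.values.max(axis=0) == pytest.approx([1.0] * 4)
        assert (np.abs(out.values) <= 1.0 + 1e-12).all()


def test_feature_frame_columns():
    row = FeatureRow("A", {"pain": 2.0}, {"pain": 4.0}, {"pain": 3}, {"pain": 5}, 20)
    frame = feature_frame([row], ["pain"])
    assert list(frame.columns) == ["pain_flare_on", "pain_flare_off", "pain_diff"]
    assert frame.loc["A", "pain_diff"] == pytest.approx(-2.0)
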