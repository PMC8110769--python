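"""Circular arithmetic, error computation, filtering and table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import serialbias as sb
from serialbias.preprocessing import SchemaError, split_orientations


def brute_acute(a, b):
    """Minimize |a - b + 180k| over k; ties broken toward +90."""
    cands = [a - b + 180.0 * k for k in range(-5, 6)]
    return min(cands, key=lambda d: (abs(d), -d))


class TestAcuteDiff:
    def test_exhaustive_integer_oracle(self):
        """All 32,400 integer orientation pairs match the brute-force oracle."""
        for a in range(0, 180, 1):
            for b in range(0, 180, 1):
                assert sb.acute_diff(a, b) == brute_acute(a, b), (a, b)

    def test_wraparound_and_identity(self):
        assert sb.acute_diff(10.0, 170.0) == 20.0
        assert sb.acute_diff(170.0, 10.0) == -20.0
        for x in (0.0, 45.3, 179.9):
            assert sb.acute_diff(x, x) == 0.0

    def test_boundary_maps_to_plus_ninety(self):
        assert sb.acute_diff(100.0, 10.0) == 90.0
        assert sb.acute_diff(10.0, 100.0) == 90.0

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-720, 720), st.floats(-720, 720))
    def test_range_periodicity_antisymmetry(self, a, b):
        d = sb.acute_diff(a, b)
        assert -90.0 < d <= 90.0
        assert sb.acute_diff(a + 180.0, b) == pytest.approx(d, abs=1e-9)
        if abs(d) < 89.999:  # away from the +90 tie-break boundary
            assert sb.acute_diff(b, a) == pytest.approx(-d, abs=1e-9)


def _table(rows):
    defaults = dict(participant="p01", experiment="E1", condition="Random",
                    block=0, rt=1.5, is_early_control=False,
                    is_rotation_break_control=False)
    out = []
    for i, r in enumerate(rows):
        row = {**defaults, "trial": i, **r}
        out.append(row)
    return pd.DataFrame(out)


class TestComputeErrors:
    def test_raw_error_and_history_predictors(self):
        table = _table([
            {"orientations": "60;40;20", "reported": 30.0},
            {"orientations": "170;10", "reported": 5.0},
        ])
        out = sb.compute_errors(table)
        assert out.loc[0, "error"] == 10.0          # reported 30, target 20
        assert out.loc[0, "delta_prev_stim"] == 20.0  # previous 40, target 20
        assert np.isnan(out.loc[0, "delta_prev_report"])  # first trial
        assert out.loc[1, "delta_prev_stim"] == -20.0
        # previous trial's report (30) vs current target (10)
        assert out.loc[1, "delta_prev_report"] == 20.0

    def test_attraction_sign_convention(self):
        # error and delta sharing a sign counts toward the previous
        # orientation: previous 40, target 20 (delta +20), report 25 (+5)
        table = _table([{"orientations": "40;20", "reported": 25.0}])
        out = sb.compute_errors(table)
        assert out.loc[0, "delta_prev_stim"] > 0 and out.loc[0, "error"] > 0

    def test_constant_offset_vanishes_after_mean_correction(self):
        rng = np.random.default_rng(0)
        targets = rng.choice(np.arange(0, 180, 20), size=50)
        table = _table([{"orientations": f"40;{t}",
                         "reported": sb.wrap_orientation(t + 7.0)}
                        for t in targets])
        out = sb.mean_correct(sb.compute_errors(table))
        np.testing.assert_allclose(out["error"], 0.0, atol=1e-9)

    def test_missing_report_flagged_not_dropped(self):
        table = _table([{"orientations": "40;20", "reported": np.nan}])
        out = sb.compute_errors(table)
        assert len(out) == 1 and bool(out.loc[0, "missing_report"])


class TestFlagOutliers:
    def test_planted_large_error_is_the_only_error_outlier(self):
        rng = np.random.default_rng(1)
        targets = rng.choice(np.arange(0, 180, 20), size=60)
        noise = rng.normal(0, 5, size=60)
        noise[30] = 80.0  # planted gross error among sigma = 5 noise
        table = _table([{"orientations": f"40;{t}",
                         "reported": sb.wrap_orientation(t + e)}
                        for t, e in zip(targets, noise)])
        out = sb.flag_outliers(sb.compute_errors(table))
        assert out["is_outlier"].sum() == 1
        assert bool(out.loc[30, "is_outlier"])
        assert bool(out.loc[31, "post_outlier"])
        assert out["post_outlier"].sum() == 1

    def test_reaction_time_boundaries_are_strict(self):
        table = _table([
            {"orientations": "40;20", "reported": 20.0, "rt": 0.4},
            {"orientations": "40;20", "reported": 20.0, "rt": 0.5},
            {"orientations": "40;20", "reported": 20.0, "rt": 10.0},
            {"orientations": "40;20", "reported": 20.0, "rt": 10.1},
        ] + [{"orientations": "40;20", "reported": 20.0}] * 8)
        out = sb.flag_outliers(sb.compute_errors(table))
        assert out["is_outlier"].tolist()[:4] == [True, False, False, True]

    def test_post_outlier_does_not_cross_blocks(self):
        table = _table([
            {"orientations": "40;20", "reported": 20.0, "rt": 0.1, "block": 0,
             "trial": 0},
            {"orientations": "40;20", "reported": 20.0, "block": 1, "trial": 0},
        ])
        out = sb.flag_outliers(sb.compute_errors(table))
        assert not out["post_outlier"].any()


class TestExcludeParticipants:
    def test_uniform_responder_excluded(self):
        rng = np.random.default_rng(2)
        rows = []
        for pid, reports in [("good", None), ("uniform", None)]:
            for i in range(200):
                t = float(rng.choice(np.arange(0, 180, 20)))
                if pid == "good":
                    rep = sb.wrap_orientation(t + rng.normal(0, 8))
                else:
                    rep = float(rng.uniform(0, 180))  # error SD ~ 180/sqrt(12)
                rows.append({"participant": pid, "trial": i,
                             "orientations": f"40;{t}", "reported": rep})
        table = sb.compute_errors(_table(rows))
        kept, excluded = sb.exclude_participants(table)
        assert excluded == ["uniform"]
        assert set(kept["participant"]) == {"good"}

    def test_below_threshold_retained_and_zero_error_keeps_all(self):
        rng = np.random.default_rng(3)
        rows = [{"participant": "p", "trial": i, "orientations": "40;90",
                 "reported": sb.wrap_orientation(90 + e)}
                for i, e in enumerate(rng.normal(0, 29, 400))]
        rows += [{"participant": "z", "trial": i, "orientations": "40;90",
                  "reported": 90.0} for i in range(50)]
        table = sb.compute_errors(_table(rows))
        _, excluded = sb.exclude_participants(table)
        assert excluded == []


class TestIO:
    def test_round_trip(self, tmp_path, e1_spec):
        table = sb.simulate_dataset(e1_spec, 2, sb.ObserverParams(), seed=1)
        path = tmp_path / "trials.csv"
        sb.write_trials(table, path)
        back = sb.read_trials(path)
        for col in ("participant", "condition", "block", "trial",
                    "is_early_control", "is_rotation_break_control"):
            assert back[col].tolist() == table[col].tolist()
        np.testing.assert_allclose(back["reported"], table["reported"])
        assert all(np.allclose(split_orientations(a), split_orientations(b))
                   for a, b in zip(back["orientations"], table["orientations"]))

    def test_missing_columns_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant": ["p"], "reported": [1.0]}).to_csv(
            path, index=False)
        with pytest.raises(SchemaError, match="condition"):
            sb.read_trials(path)

    def test_column_map_adapts_external_headers(self, tmp_path, e1_spec):
        table = sb.simulate_dataset(e1_spec, 1, sb.ObserverParams(), seed=2)
        renamed = table.rename(columns={"participant": "subj",
                                        "reported": "resp_ori",
                                        "orientations": "seq"})
        path = tmp_path / "external.csv"
        renamed.to_csv(path, index=False)
        mapped = sb.read_trials(path, column_map={
            "subj": "participant", "resp_ori": "reported", "seq": "orientations"})
        sb.write_trials(table, tmp_path / "native.csv")
        clean_a, _ = sb.preprocess(mapped)
        clean_b, _ = sb.preprocess(sb.read_trials(tmp_path / "native.csv"))
        np.testing.assert_allclose(clean_a["error"], clean_b["error"])


class TestCleanTable:
    def test_no_controls_outliers_or_followers_and_centred(self, regime_table):
        clean, log = sb.preprocess(regime_table)
        assert not clean["is_early_control"].any()
        assert not clean["is_rotation_break_control"].any()
        assert not clean["is_outlier"].any()
        assert not clean["post_outlier"].any()
        assert 0 < len(clean) < len(regime_table)
        means = clean.groupby(["participant", "condition"])["error"].mean()
        assert np.abs(means).max() < 1e-9

    def test_filtering_is_idempotent(self, regime_table):
        # the 3-SD rule is one-pass: re-applying the filter to the already
        # clean table removes nothing further
        table = sb.flag_outliers(sb.compute_errors(regime_table))
        once = sb.clean_trials(table)
        twice = sb.clean_trials(once)
        assert twice[once.columns].equals(once)

    def test_prev_report_chain_breaks_at_removed_trials(self, regime_table):
        table = sb.flag_outliers(sb.compute_errors(regime_table))
        clean = sb.clean_trials(table, chain_prev_report=False)
        removed = table[table["is_early_control"] | table["is_outlier"]
                        | table["post_outlier"]
                        | table["is_rotation_break_control"]]
        # any retained trial right after a removed one has no SD predictor
        for (pid, blk, tr) in removed[["participant", "block", "trial"]
                                      ].itertuples(index=False):
            follower = clean[(clean["participant"] == pid)
                             & (clean["block"] == blk)
                             & (clean["trial"] == tr + 1)]
            assert follower["delta_prev_report"].isna().all()
        chained = sb.clean_trials(table, chain_prev_report=True)
        assert chained["delta_prev_report"].notna().sum() \
            > clean["delta_prev_report"].notna().sum()

    def test_null_outlier_rate_below_five_percent(self, null_table):
        _, log = sb.preprocess(null_table)
        assert log["outlier_rate"] < 0.05
        assert log["excluded_participants"] == []
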