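import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dceradiomics.temporal_stats import (LmmResult, StatsConfig, bh_fdr,
                                         cluster_profiles, fit_lmm,
                                         linkage_to_nested, screen_features,
                                         significant_features, zscore_profile)


def long_rows(values_by_subject, feature="f", roi="tumor", visit=1):
    rows = []
    for subj, vals in values_by_subject.items():
        for phase, v in enumerate(vals, start=1):
            rows.append((subj, visit, roi, phase, feature, v, False))
    return pd.DataFrame(rows, columns=["subject", "visit", "roi", "phase",
                                       "feature", "value", "flag"])


class TestFitLmm:
    def test_recovers_within_subject_slope(self):
        rng = np.random.default_rng(0)
        table = long_rows({
            "a": [2.0 * p + rng.normal(0, 1e-6) for p in range(1, 8)],
            "b": [2.0 * p + 10 + rng.normal(0, 1e-6) for p in range(1, 8)],
        })
        res = fit_lmm(table)
        assert res.converged and not res.excluded
        assert res.estimate == pytest.approx(2.0, abs=1e-3)
        assert res.p < 1e-6

    def test_constant_feature_excluded(self):
        table = long_rows({"a": [3.0] * 7, "b": [3.0] * 7})
        res = fit_lmm(table)
        assert res.excluded and np.isnan(res.p)

    def test_single_subject_excluded(self):
        table = long_rows({"a": list(range(7))})
        assert fit_lmm(table).excluded

    def test_flagged_rows_are_dropped(self):
        table = long_rows({"a": list(range(1, 8)), "b": list(range(2, 9))})
        table.loc[:, "flag"] = True
        assert fit_lmm(table).excluded

    def test_matches_lmerTest_satterthwaite(self, tmp_path):
        # independent oracle: R lmerTest with the same REML model
        rng = np.random.default_rng(42)
        rows = {}
        for s in range(6):
            u = rng.normal(0, 1.0)
            rows[f"s{s}"] = [0.3 * p + u + rng.normal(0, 0.5) for p in range(1, 8)]
        table = long_rows(rows)
        csv = tmp_path / "fixture.csv"
        table.to_csv(csv, index=False)
        res = fit_lmm(table)
        rcode = (
            'suppressMessages(library(lmerTest));'
            f'd <- read.csv("{csv}");'
            'm <- lmer(value ~ phase + (1|subject), data=d, REML=TRUE);'
            's <- summary(m)$coefficients;'
            'cat(sprintf("%.10f %.10g %.4f", s[2,1], s[2,5], s[2,3]))'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        slope_r, p_r, df_r = (float(x) for x in out.stdout.split())
        assert res.estimate == pytest.approx(slope_r, rel=1e-5)
        assert res.p == pytest.approx(p_r, rel=1e-3)
        assert df_r == pytest.approx(42 - 6 - 1)  # residual df = Satterthwaite here

    def test_categorical_coding_detects_nonmonotone_profile(self):
        rng = np.random.default_rng(3)
        peak = [0, 0, 1, 5, 1, 0, 0]
        rows = {f"s{s}": [peak[p] + rng.normal(0, 0.3) for p in range(7)]
                for s in range(6)}
        table = long_rows(rows)
        res = fit_lmm(table, StatsConfig(timepoint_coding="categorical"))
        assert res.converged and res.p < 0.01

    def test_visit_variant_runs(self):
        rng = np.random.default_rng(4)
        frames = []
        for visit in (1, 2):
            rows = {f"s{s}": [0.5 * p + rng.normal(0, 0.5) for p in range(1, 8)]
                    for s in range(4)}
            frames.append(long_rows(rows, visit=visit))
        table = pd.concat(frames, ignore_index=True)
        res = fit_lmm(table, StatsConfig(formula="patient+visit"))
        assert not res.excluded and 0 <= res.p <= 1


class TestBhFdr:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    def test_q_dominates_p_and_is_capped(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)


class TestSignificance:
    def test_joint_rule(self):
        cfg = StatsConfig()
        results = [
            LmmResult("in", 1.0, p=0.01, q=0.04, converged=True),
            LmmResult("out_q", 1.0, p=0.01, q=0.08, converged=True),
            LmmResult("out_excluded", 1.0, p=0.001, q=0.001, converged=False,
                      excluded=True),
        ]
        assert significant_features(results, cfg) == {"in"}


class TestProfilesAndClusters:
    def test_zscore_three_phase_toy(self):
        rows = []
        for subj in ("a", "b"):
            for phase, v in enumerate([1.0, 2.0, 3.0], start=1):
                rows.append((subj, 1, "tumor", phase, "f", v, False))
        df = pd.DataFrame(rows, columns=["subject", "visit", "roi", "phase",
                                         "feature", "value", "flag"])
        prof, flagged = zscore_profile(df, "f")
        np.testing.assert_allclose(prof, [-1.0, 0.0, 1.0])
        assert not flagged
        assert prof.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.std(ddof=1) == pytest.approx(1.0)

    def test_constant_profile_flagged_zeros(self):
        df = long_rows({"a": [5.0] * 7, "b": [5.0] * 7})
        prof, flagged = zscore_profile(df, "f")
        assert flagged and np.all(prof == 0)

    def test_separated_templates_split_perfectly(self):
        rng = np.random.default_rng(0)
        up = np.linspace(-1, 1, 7)
        profiles = {}
        for i in range(10):
            profiles[f"up{i}"] = up + rng.normal(0, 0.01, 7)
            profiles[f"down{i}"] = -up + rng.normal(0, 0.01, 7)
        clusters, Z = cluster_profiles(profiles, k=2)
        ups = {clusters[f"up{i}"] for i in range(10)}
        downs = {clusters[f"down{i}"] for i in range(10)}
        assert len(ups) == 1 and len(downs) == 1 and ups != downs

    def test_automatic_k_finds_two_separated_groups(self):
        rng = np.random.default_rng(1)
        up = np.linspace(-1, 1, 7)
        profiles = {f"u{i}": up + rng.normal(0, 0.02, 7) for i in range(8)}
        profiles.update({f"d{i}": -up + rng.normal(0, 0.02, 7) for i in range(8)})
        clusters, _ = cluster_profiles(profiles, k=None)
        assert len(set(clusters.values())) == 2

    def test_identical_profiles_merge_at_zero_height(self):
        profiles = {"a": np.arange(7.0), "b": np.arange(7.0), "c": np.arange(7.0) * -1}
        _, Z = cluster_profiles(profiles, k=2)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_k1_is_single_cluster(self):
        profiles = {f"f{i}": np.random.default_rng(i).normal(size=7) for i in range(5)}
        clusters, _ = cluster_profiles(profiles, k=1)
        assert set(clusters.values()) == {1}

    def test_linkage_tree_export_contains_all_leaves(self):
        profiles = {"a": np.arange(7.0), "b": -np.arange(7.0), "c": np.ones(7)}
        clusters, Z = cluster_profiles(profiles, k=2)
        nested = linkage_to_nested(Z, list(profiles))
        flat = []

        def walk(x):
            if isinstance(x, list):
                for y in x:
                    walk(y)
            else:
                flat.append(x)

        walk(nested)
        assert sorted(flat) == ["a", "b", "c"]


class TestScreen:
    def test_screen_separates_signal_null_and_constant(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(7):
            u = rng.normal(0, 0.5)
            for phase in range(1, 8):
                rows.append((f"s{s}", 1, "tumor", phase, "signal",
                             2.0 * phase + u + rng.normal(0, 0.5), False))
                rows.append((f"s{s}", 1, "tumor", phase, "null",
                             rng.normal(), False))
                rows.append((f"s{s}", 1, "tumor", phase, "constant", 1.0, False))
        table = pd.DataFrame(rows, columns=["subject", "visit", "roi", "phase",
                                            "feature", "value", "flag"])
        res = screen_features(table, roi="tumor").set_index("feature")
        assert res.loc["signal", "significant"]
        assert not res.loc["null", "significant"]
        assert res.loc["constant", "excluded"]

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=1.5)
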