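"""Normality-gated decision tree, Grubbs screening, and report contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from patchkit.exceptions import DesignError
from patchkit.stats import (
    grubbs_critical,
    remove_outliers,
    select_and_run,
)


def _two_groups(rng, n=12, shift=0.0, dist="normal"):
    if dist == "normal":
        wt, ko = rng.normal(0, 1, n), rng.normal(shift, 1, n)
    else:
        wt, ko = rng.lognormal(0, 1.5, n), rng.lognormal(shift, 1.5, n)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(2 * n)],
        "genotype": ["WT"] * n + ["KO"] * n,
        "value": np.concatenate([wt, ko]),
    })


class TestGate:
    def test_normal_samples_take_t_test(self, rng):
        rep = select_and_run(_two_groups(rng))
        assert rep.test_name in ("t-test", "welch-t-test")
        assert rep.p_value > 0.05
        assert any("parametric" in line for line in rep.trace)

    def test_heavy_tailed_samples_take_mann_whitney(self, rng):
        rep = select_and_run(_two_groups(rng, n=20, dist="lognormal"))
        assert rep.test_name == "mann-whitney"

    def test_three_groups_take_anova_or_kruskal(self, rng):
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(36)],
            "genotype": ["A"] * 12 + ["B"] * 12 + ["C"] * 12,
            "value": rng.normal(0, 1, 36),
        })
        rep = select_and_run(df)
        assert rep.test_name in ("one-way-anova", "kruskal-wallis")
        assert rep.posthoc is not None and len(rep.posthoc) == 3

    def test_bonferroni_is_min_one_raw_times_m(self, rng):
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(36)],
            "genotype": ["A"] * 12 + ["B"] * 12 + ["C"] * 12,
            "value": rng.normal(0, 1, 36),
        })
        rep = select_and_run(df)
        m = len(rep.posthoc)
        for _, row in rep.posthoc.iterrows():
            assert row["p_bonf"] == pytest.approx(min(1.0, row["p_raw"] * m))
            assert row["p_bonf"] >= row["p_raw"]

    def test_empty_design_cell_raises_named_error(self, rng):
        df = _two_groups(rng)
        df = df[~((df.genotype == "KO") & (df.index >= 14))]
        with pytest.raises(DesignError, match="KO"):
            select_and_run(df)

    def test_decision_is_deterministic(self, rng):
        df = _two_groups(rng)
        a, b = select_and_run(df), select_and_run(df)
        assert a.trace == b.trace
        assert a.p_value == b.p_value

    def test_gg_correction_shrinks_df_under_nonsphericity(self, rng):
        rows = []
        for i in range(12):
            base = rng.normal(0, 1)
            for j, lev in enumerate(["s1", "s2", "s3"]):
                # noise grows with level: guaranteed non-sphericity
                rows.append({"cell_id": f"c{i}", "step": lev,
                             "value": base + j + rng.normal(0, 0.05 * 4**j)})
        rep = select_and_run(pd.DataFrame(rows), between=[], within="step")
        assert rep.test_name == "rm-anova"
        assert rep.sphericity["gg_applied"]
        assert rep.sphericity["gg_epsilon"] < 1.0
        df1, df2 = rep.df
        assert df1 < 2.0 and df2 < 22.0  # uncorrected would be (2, 22)

    def test_mixed_design_reports_between_effect(self, rng):
        rows = []
        for i in range(20):
            g = "WT" if i < 10 else "KO"
            base = rng.normal(0 if g == "WT" else 3.0, 1)
            for j, lev in enumerate(["s1", "s2"]):
                rows.append({"cell_id": f"c{i}", "genotype": g, "step": lev,
                             "value": base + j + rng.normal(0, 0.3)})
        rep = select_and_run(pd.DataFrame(rows), between=["genotype"],
                             within="step")
        assert rep.test_name == "mixed-anova:genotype"
        assert rep.p_value < 0.01


class TestGrubbs:
    def test_planted_outlier_removed(self):
        kept, removed = remove_outliers([10, 11, 9, 10, 50])
        assert list(removed) == [50.0]
        assert sorted(kept) == [9, 10, 10, 11]

    def test_critical_value_against_direct_formula(self):
        # n=5, alpha=0.05: t-based closed form evaluated independently
        n, alpha = 5, 0.05
        t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical(5) == pytest.approx(expected)
        g = abs(50 - np.mean([10, 11, 9, 10, 50])) / np.std(
            [10, 11, 9, 10, 50], ddof=1)
        assert g > expected  # hence the removal above

    def test_homogeneous_sample_untouched(self):
        kept, removed = remove_outliers([10.0, 10.5, 9.5, 10.2, 9.8])
        assert removed.size == 0
        assert kept.size == 5

    def test_small_sample_noop_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept, removed = remove_outliers([1.0, 2.0])
        assert kept.size == 2 and removed.size == 0
        assert any("skipped" in r.message for r in caplog.records)
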