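"""Moderated-t machinery: contrast fits, hyperparameter recovery, shrinkage, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ibmtpath import (
    Comparison,
    EBHyper,
    ExpressionStudy,
    SimulationConfig,
    bh_fdr,
    estimate_eb_hyperparameters,
    fit_gene_stats,
    generate_study,
    moderated_test,
)
from ibmtpath.ibmt import InsufficientReplicationError


def _study_from_diffs(diff_rows):
    """Build a paired study whose per-subject differences equal diff_rows."""
    diffs = np.atleast_2d(np.asarray(diff_rows, dtype=float))
    n_probes, n_subj = diffs.shape
    values = np.zeros((n_probes, 2 * n_subj))
    design = []
    cols = []
    for j in range(n_subj):
        values[:, 2 * j] = 8.0 + diffs[:, j]   # exercised
        values[:, 2 * j + 1] = 8.0             # control
        design.append((f"s{j}_ex", f"s{j}", "M", "exercised", "4h"))
        design.append((f"s{j}_ctl", f"s{j}", "M", "control", "4h"))
        cols += [f"s{j}_ex", f"s{j}_ctl"]
    design = (
        pd.DataFrame(design, columns=["sample_id", "subject_id", "sex", "arm", "time"])
        .set_index("sample_id")
    )
    values = pd.DataFrame(values, index=[f"P{i}" for i in range(n_probes)], columns=cols)
    return ExpressionStudy(values=values, design=design)


PAIRED = Comparison(
    "m4", "paired",
    {"sex": "M", "time": "4h", "arm": "exercised"},
    {"sex": "M", "time": "4h", "arm": "control"},
)


class TestFitGeneStats:
    def test_paired_textbook_oracle(self):
        """Differences (1.0, 1.2, 0.8): b=1, s2=0.04, d=2, ordinary t=8.660."""
        study = _study_from_diffs([[1.0, 1.2, 0.8]])
        stats = fit_gene_stats(study, PAIRED)
        row = stats.iloc[0]
        assert row["b"] == pytest.approx(1.0)
        assert row["s2"] == pytest.approx(0.04)
        assert row["d"] == 2
        assert row["u"] == pytest.approx(1 / np.sqrt(3))
        t = row["b"] / (row["u"] * np.sqrt(row["s2"]))
        assert t == pytest.approx(8.660254, abs=1e-6)

    def test_unpaired_textbook_oracle(self):
        """(1,2,3) vs (2,3,4): b=-1, pooled s2=1, d=4, t=-1.2247."""
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]],
            index=["P1"],
            columns=[f"s{j}" for j in range(6)],
        )
        design = (
            pd.DataFrame(
                [
                    ("s0", "A", "M", "control", "4h"),
                    ("s1", "B", "M", "control", "4h"),
                    ("s2", "C", "M", "control", "24h"),
                    ("s3", "D", "F", "control", "4h"),
                    ("s4", "E", "F", "control", "4h"),
                    ("s5", "G", "F", "control", "24h"),
                ],
                columns=["sample_id", "subject_id", "sex", "arm", "time"],
            ).set_index("sample_id")
        )
        study = ExpressionStudy(values=values, design=design)
        comp = Comparison("mf", "unpaired", {"sex": "M"}, {"sex": "F"})
        row = fit_gene_stats(study, comp).iloc[0]
        assert row["b"] == pytest.approx(-1.0)
        assert row["s2"] == pytest.approx(1.0)
        assert row["d"] == 4
        assert row["u"] == pytest.approx(np.sqrt(2 / 3))
        t = row["b"] / (row["u"] * np.sqrt(row["s2"]))
        assert t == pytest.approx(-1.224745, abs=1e-6)
        assert row["a"] == pytest.approx(2.5)

    def test_single_pair_insufficient_replication(self):
        study = _study_from_diffs([[1.0]])
        with pytest.raises(InsufficientReplicationError, match="insufficient replication"):
            fit_gene_stats(study, PAIRED)


class TestHyperparameters:
    def test_zero_residual_limit_gives_infinite_d0(self):
        rng = np.random.default_rng(0)
        stats_df = pd.DataFrame(
            {
                "b": rng.normal(size=200),
                "u": 0.5,
                "s2": 0.05,             # all identical
                "d": 4.0,
                "a": rng.uniform(4, 14, 200),
                "sign": 1.0,
            }
        )
        hyper = estimate_eb_hyperparameters(stats_df)
        assert np.isinf(hyper.d0)
        # full-shrinkage prior equals the (flat) trend of the corrected log s2
        assert np.all(hyper.s0_sq > 0)

    def test_parameter_recovery_on_generator(self):
        """d0 and s0^2 recovered from a constant-prior simulation (one seed)."""
        config = SimulationConfig(
            seed=21, n_probes=20000, groups=(("M", "4h", 5),),
            d0_true=4.0, s0_sq=0.05, s0_slope=0.0, de_fraction=0.0,
            sex_de_fraction=0.0,
        )
        study, _ = generate_study(config)
        stats_df = fit_gene_stats(study, PAIRED)
        hyper = estimate_eb_hyperparameters(stats_df)
        assert 3.0 <= hyper.d0 <= 5.0
        assert np.median(hyper.s0_sq) == pytest.approx(0.05, rel=0.2)

    def test_probe_floor_enforced(self):
        stats_df = pd.DataFrame(
            {"b": [0.1] * 10, "u": 0.5, "s2": 0.05, "d": 4.0, "a": 8.0, "sign": 1.0}
        )
        with pytest.raises(ValueError, match="100"):
            estimate_eb_hyperparameters(stats_df)

    def test_zero_variance_probes_still_moderated(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 500) * 0.05 / 4
        s2[:5] = 0.0
        stats_df = pd.DataFrame(
            {
                "b": rng.normal(size=500), "u": 0.5, "s2": s2, "d": 4.0,
                "a": rng.uniform(4, 14, 500), "sign": 1.0,
            }
        )
        hyper = estimate_eb_hyperparameters(stats_df)
        mod = moderated_test(stats_df, hyper)
        assert mod["p"].iloc[:5].notna().all()  # tested through the prior


class TestModeratedTest:
    def _stats(self):
        return pd.DataFrame(
            {"b": [1.0], "u": [1 / np.sqrt(3)], "s2": [0.04], "d": [2.0],
             "a": [8.0], "sign": [1.0]},
            index=["P1"],
        )

    def test_worked_shrinkage_example(self):
        """d0=3, s0^2=0.09: posterior variance 0.07, t=6.546, p~1.2e-3."""
        stats_df = self._stats()
        hyper = EBHyper(d0=3.0, s0_sq=pd.Series([0.09], index=["P1"]), span=0.75)
        mod = moderated_test(stats_df, hyper)
        row = mod.iloc[0]
        assert row["s2_post"] == pytest.approx(0.07)
        assert row["t"] == pytest.approx(6.546537, abs=1e-5)
        assert row["df"] == 5
        assert row["p"] == pytest.approx(1.2455792530624264e-3, rel=1e-9)

    def test_d0_zero_reduces_to_ordinary_t(self):
        stats_df = self._stats()
        hyper = EBHyper(d0=0.0, s0_sq=pd.Series([123.0], index=["P1"]), span=0.75)
        mod = moderated_test(stats_df, hyper)
        row = mod.iloc[0]
        assert row["s2_post"] == pytest.approx(0.04)
        assert row["df"] == 2
        t = 1.0 / ((1 / np.sqrt(3)) * np.sqrt(0.04))
        assert row["p"] == pytest.approx(2 * sps.t.sf(t, 2), rel=1e-12)

    def test_d0_infinite_full_shrinkage_normal_tail(self):
        stats_df = self._stats()
        hyper = EBHyper(d0=np.inf, s0_sq=pd.Series([0.09], index=["P1"]), span=0.75)
        mod = moderated_test(stats_df, hyper)
        row = mod.iloc[0]
        assert row["s2_post"] == pytest.approx(0.09)
        t = 1.0 / ((1 / np.sqrt(3)) * np.sqrt(0.09))
        assert row["p"] == pytest.approx(2 * sps.norm.sf(t), rel=1e-12)

    def test_shrinkage_convexity(self, small_experiment, paired_comparison):
        study = small_experiment[0]
        stats_df = fit_gene_stats(study, paired_comparison)
        hyper = estimate_eb_hyperparameters(stats_df)
        mod = moderated_test(stats_df, hyper)
        lo = np.minimum(stats_df["s2"], hyper.s0_sq)
        hi = np.maximum(stats_df["s2"], hyper.s0_sq)
        assert ((mod["s2_post"] >= lo - 1e-12) & (mod["s2_post"] <= hi + 1e-12)).all()

    def test_null_moderated_t_follows_t_distribution(self):
        """Under a known prior, t~ follows t(d0+d): KS non-rejection at 0.001."""
        config = SimulationConfig(
            seed=33, n_probes=20000, groups=(("M", "4h", 4),),
            d0_true=4.0, s0_sq=0.05, s0_slope=0.0, de_fraction=0.0,
            sex_de_fraction=0.0,
        )
        study, truth = generate_study(config)
        stats_df = fit_gene_stats(study, PAIRED)
        hyper = EBHyper(
            d0=4.0,
            s0_sq=pd.Series(truth.probes["s0_sq_true"].to_numpy(), index=stats_df.index),
            span=0.75,
        )
        mod = moderated_test(stats_df, hyper)
        ks = sps.kstest(mod["t"], "t", args=(4.0 + 3.0,))
        assert ks.pvalue > 0.001


class TestBHFdr:
    def test_worked_step_up_vector(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.7]), [0.7])
        assert bh_fdr([]).size == 0

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=200),
    )
    def test_matches_brute_force_step_up(self, ps):
        """q_(i) = min_{j>=i} p_(j) * m / j against a direct double loop."""
        p = np.asarray(ps)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        m = len(p)
        brute = np.empty(m)
        for rank_i in range(m):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_i, m)
            ]
            brute[order[rank_i]] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, brute, rtol=1e-12)

    def test_q_dominates_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 300)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
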