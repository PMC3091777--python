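"""Enrichment machinery: GMT IO, scores, IRLS against an independent ML fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ibmtpath.lrpath import (
    DegenerateScoresError,
    GeneSet,
    GeneSetCollection,
    build_significance_scores,
    enrichment_matrix,
    read_gmt,
    run_lrpath,
    write_gmt,
    _logistic_irls,
)
from ibmtpath.study_model import FormatError


class TestGmtIO:
    def test_universe_intersection(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\tg3\n")
        coll = read_gmt(path, universe=["g1", "g2"])
        assert coll["S1"].members == ("g1", "g2")

    def test_duplicate_set_id_rejected(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\ta\tg1\tg2\tg3\nS1\tb\tg4\tg5\tg6\n")
        with pytest.raises(FormatError, match="S1"):
            read_gmt(path)

    def test_short_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tonly-two-fields\n")
        with pytest.raises(FormatError, match=":1"):
            read_gmt(path)

    def test_synthetic_gmt_round_trips(self, tmp_path, small_experiment):
        _, sets, _, _ = small_experiment
        p1 = tmp_path / "a.gmt"
        p2 = tmp_path / "b.gmt"
        write_gmt(sets, p1)
        back = read_gmt(p1)
        write_gmt(back, p2)
        assert p1.read_text() == p2.read_text()
        assert [gs.set_id for gs in back] == [gs.set_id for gs in sets]


class TestSignificanceScores:
    def _frames(self, p, sign, a, probes=None):
        idx = probes or [f"P{i}" for i in range(len(p))]
        mod = pd.DataFrame({"p": p}, index=idx)
        gstats = pd.DataFrame({"sign": sign, "a": a}, index=idx)
        return mod, gstats

    def test_signed_log_p_closed_form(self):
        mod, gstats = self._frames([0.001, 0.001, 1.0], [1.0, -1.0, 1.0], [8, 8, 8])
        scores = build_significance_scores(mod, gstats, level="probe")
        np.testing.assert_allclose(
            scores["x"].to_numpy(), [6.907755, -6.907755, 0.0], atol=1e-6
        )

    def test_p_of_one_scores_zero_either_direction(self):
        mod, gstats = self._frames([1.0, 1.0], [1.0, -1.0], [8, 8])
        scores = build_significance_scores(mod, gstats, level="probe")
        assert (scores["x"] == 0.0).all()

    def test_gene_level_picks_highest_intensity_probe(self):
        mod, gstats = self._frames([0.01, 0.5], [1.0, -1.0], [6.1, 9.3])
        gene_map = pd.Series(["G1", "G1"], index=["P0", "P1"])
        scores = build_significance_scores(mod, gstats, gene_map=gene_map, level="gene")
        assert list(scores.index) == ["G1"]
        assert scores.loc["G1", "probe"] == "P1"  # a=9.3 wins

    def test_extreme_p_clamped_before_log(self):
        mod, gstats = self._frames([1e-320], [1.0], [8.0])
        scores = build_significance_scores(mod, gstats, level="probe")
        assert np.isfinite(scores["x"]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_significance_scores(pd.DataFrame({"p": []}), pd.DataFrame())


def _random_instance(rng, n_genes=None):
    n = n_genes or int(rng.integers(40, 500))
    x = rng.normal(size=n)
    k = int(rng.integers(5, max(6, n // 4)))
    members = rng.choice(n, size=k, replace=False)
    y = np.zeros(n)
    y[members] = 1.0
    return x, y


class TestIrlsOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_ml_fit(self, seed):
        """beta1, SE and Wald p agree with an independent ML logistic fit."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            x, y = _random_instance(rng)
            beta, se, converged = _logistic_irls(x, y)
            if not converged or abs(beta[1]) > 20:
                continue
            ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton")
            np.testing.assert_allclose(beta, ref.params, rtol=1e-6, atol=1e-9)
            np.testing.assert_allclose(se, ref.bse, rtol=1e-6, atol=1e-9)

    def test_frozen_small_fixture(self):
        """20-gene, 5-member fixture: slope/p match the independent fit to 1e-6."""
        rng = np.random.default_rng(2024)
        x = rng.normal(size=20)
        y = np.zeros(20)
        y[[0, 3, 7, 11, 19]] = 1.0
        beta, se, converged = _logistic_irls(x, y)
        assert converged
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton")
        np.testing.assert_allclose(beta[1], ref.params[1], rtol=1e-6)
        np.testing.assert_allclose(se[1], ref.bse[1], rtol=1e-6)


class TestRunLrpath:
    def _scores(self, rng, n=300):
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_whole_universe_set_flagged_unstable(self):
        rng = np.random.default_rng(0)
        scores = self._scores(rng, 60)
        coll = GeneSetCollection()
        coll.add(GeneSet("ALL", "everything", tuple(scores.index)))
        out = run_lrpath(scores, coll, min_size=10, max_size=100)
        assert out.loc["ALL", "status"] == "unstable"
        assert np.isnan(out.loc["ALL", "p"])

    def test_constant_scores_rejected(self):
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(50)])
        coll = GeneSetCollection()
        coll.add(GeneSet("S", "s", tuple(f"g{i}" for i in range(15))))
        with pytest.raises(DegenerateScoresError):
            run_lrpath(scores, coll)

    def test_size_window_filters_sets(self):
        rng = np.random.default_rng(1)
        scores = self._scores(rng, 200)
        coll = GeneSetCollection()
        coll.add(GeneSet("TINY", "too small", tuple(f"g{i}" for i in range(5))))
        coll.add(GeneSet("OK", "kept", tuple(f"g{i}" for i in range(40))))
        out = run_lrpath(scores, coll, min_size=10, max_size=100)
        assert list(out.index) == ["OK"]

    def test_score_antisymmetry(self):
        """Negating all signs negates beta1 for every set, |beta1| unchanged."""
        rng = np.random.default_rng(3)
        scores = self._scores(rng, 250)
        coll = GeneSetCollection()
        for k in range(5):
            members = rng.choice(scores.index, size=30, replace=False)
            coll.add(GeneSet(f"S{k}", "s", tuple(members)))
        fwd = run_lrpath(scores, coll)
        rev = run_lrpath(-scores, coll)
        np.testing.assert_allclose(
            fwd["beta1"].to_numpy(), -rev["beta1"].to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(fwd["p"].to_numpy(), rev["p"].to_numpy(), rtol=1e-6)

    def test_permuting_scores_destroys_planted_enrichment(
        self, small_experiment, paired_comparison
    ):
        from ibmtpath import (
            build_significance_scores, estimate_eb_hyperparameters,
            fit_gene_stats, moderated_test,
        )
        study, sets, _, truth = small_experiment
        stats_df = fit_gene_stats(study, paired_comparison)
        mod = moderated_test(stats_df, estimate_eb_hyperparameters(stats_df))
        scores = build_significance_scores(mod, stats_df)
        loaded = list(truth.sets.index[truth.sets["is_loaded"]])
        enr = run_lrpath(scores, sets)
        assert (enr.loc[loaded, "p"] < 1e-4).all()
        rng = np.random.default_rng(99)
        perm = pd.Series(
            rng.permutation(scores["x"].to_numpy()), index=scores.index
        )
        enr_perm = run_lrpath(perm, sets)
        assert enr_perm.loc[loaded, "p"].median() > 0.1


class TestEnrichmentMatrix:
    def _result(self, rows):
        return pd.DataFrame(
            rows,
            columns=["set_id", "name", "n", "beta1", "odds_ratio",
                     "direction", "p", "status", "fdr", "enriched"],
        ).set_index("set_id")

    def test_signed_log10_entries_and_fill(self):
        r1 = self._result([
            ("A", "a", 20, 1.0, np.e, "up", 0.001, "ok", 0.002, True),
            ("B", "b", 20, -0.5, 0.6, "down", 0.01, "ok", 0.01, True),
        ])
        r2 = self._result([
            ("A", "a", 20, -2.0, 0.1, "down", 0.1, "ok", 0.2, False),
        ])
        mat = enrichment_matrix({"c1": r1, "c2": r2})
        assert mat.loc["A", "c1"] == pytest.approx(3.0)
        assert mat.loc["B", "c1"] == pytest.approx(-2.0)
        assert mat.loc["B", "c2"] == 0.0  # absent pair fills with zero
        assert list(mat.columns) == ["c1", "c2"]

    def test_five_comparison_shape(self, small_experiment):
        from ibmtpath import (
            DEFAULT_COMPARISONS, build_significance_scores,
            estimate_eb_hyperparameters, fit_gene_stats, moderated_test,
        )
        study, sets, _, _ = small_experiment
        results = {}
        for comp in DEFAULT_COMPARISONS:
            stats_df = fit_gene_stats(study, comp)
            mod = moderated_test(stats_df, estimate_eb_hyperparameters(stats_df))
            results[comp.name] = run_lrpath(
                build_significance_scores(mod, stats_df), sets
            )
        mat = enrichment_matrix(results)
        assert list(mat.columns) == [c.name for c in DEFAULT_COMPARISONS]
        assert mat.shape[1] == 5
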