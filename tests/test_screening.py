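"""Normalization, pruning, permutation testing and classification."""

import numpy as np
import pandas as pd
import pytest

from ecoqad.containers import AbundanceTable
from ecoqad.screening import (
    ScreenConfig,
    classify_association,
    co_occurrence_plots,
    compare_stages,
    css_normalize,
    permutation_pvalue,
    proportions_by_type,
    prune_variables,
    screen_all,
    split_stages,
)


def make_table(values, groups=None, kinds=None):
    values = pd.DataFrame(values)
    values.index = [f"p{i}" for i in range(len(values))]
    cols = values.columns
    return AbundanceTable(
        values=values,
        groups=pd.Series(groups or {c: "Bacteria" for c in cols}),
        gradient=pd.Series(np.arange(len(values)), index=values.index),
        kind=pd.Series(kinds or {c: "count" for c in cols}),
    )


class TestCssNormalize:
    def test_hand_computed_example(self):
        counts = pd.DataFrame([[1, 2, 3, 4]])
        out = css_normalize(counts, 0.5)
        # median of positives = 2.5, scaling sum = 1 + 2 = 3
        assert np.allclose(out.to_numpy(),
                           [[1000 / 3, 2000 / 3, 1000.0, 4000 / 3]])

    def test_constant_sample(self):
        out = css_normalize(pd.DataFrame([[5, 5, 5, 5]]), 0.5)
        assert np.allclose(out.to_numpy(), 250.0)

    def test_all_zero_sample_left_unscaled_with_warning(self):
        counts = pd.DataFrame([[0, 0, 0], [1, 2, 3]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = css_normalize(counts, 0.5)
        assert np.allclose(out.iloc[0], 0.0)

    def test_rejects_negative_counts_and_bad_quantile(self):
        with pytest.raises(ValueError):
            css_normalize(pd.DataFrame([[-1, 2]]), 0.5)
        with pytest.raises(ValueError):
            css_normalize(pd.DataFrame([[1, 2]]), 1.5)


class TestPruning:
    def test_unique_value_threshold_is_inclusive(self, rng):
        n = 40
        tbl = make_table({
            "v15": np.r_[np.arange(15), np.zeros(n - 15)],
            "v16": np.r_[np.arange(16), np.zeros(n - 16)],
            "const": np.ones(n),
        })
        kept = prune_variables(tbl, min_unique=16)
        assert kept == ["v16"]

    def test_co_occurrence_rules(self):
        n = 135
        a = np.r_[np.ones(15), np.zeros(n - 15)]
        b = np.ones(n)
        taxon = np.r_[np.ones(20), np.zeros(n - 20)]
        env1, env2 = np.arange(n, dtype=float), np.arange(n, dtype=float) * 2
        tbl = make_table(
            {"a": a, "b": b, "taxon": taxon, "env1": env1, "env2": env2},
            kinds={"a": "count", "b": "count", "taxon": "count",
                   "env1": "measurement", "env2": "measurement"})
        # two taxa jointly present on only 15 plots -> rejected
        assert co_occurrence_plots("a", "b", tbl) is None
        # taxon vs environment -> the taxon's 20 presence plots
        assert len(co_occurrence_plots("taxon", "env1", tbl)) == 20
        # two environment variables -> all plots
        assert len(co_occurrence_plots("env1", "env2", tbl)) == n


class TestPermutationTest:
    def test_perfect_dependence_reaches_minimum_p(self):
        x = np.arange(100.0)
        p_xy, p_yx = permutation_pvalue(x, x, n_perm=999, seed=0)
        assert p_xy == 0.001 and p_yx == 0.001  # add-one lower bound

    def test_add_one_estimator_never_returns_zero(self, rng):
        x = rng.normal(size=30)
        p_xy, p_yx = permutation_pvalue(x, rng.normal(size=30), n_perm=99, seed=1)
        assert p_xy >= 1 / 100 and p_yx >= 1 / 100


class TestClassification:
    @pytest.mark.parametrize("p_q, m, rho, p_rho, expected", [
        (0.01, 0.6, 0.8, 0.001, "positive"),
        (0.01, -0.5, -0.7, 0.001, "negative"),
        (0.01, 0.05, 0.1, 0.4, "non-monotonic"),
        (0.2, 0.9, 0.9, 0.001, "not-significant"),
        (0.01, -0.2, 0.5, 0.01, "positive"),  # sign conflict resolved by rho
    ])
    def test_rule_table(self, p_q, m, rho, p_rho, expected):
        assert classify_association(p_q, m, rho, p_rho) == expected

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_association(0.01, np.nan, 0.5, 0.01)


class TestScreenAll:
    @pytest.fixture(scope="class")
    def env_table(self):
        rng = np.random.default_rng(3)
        n = 40
        values = {f"v{i}": rng.normal(size=n) for i in range(5)}
        tbl = make_table(values, kinds={f"v{i}": "measurement" for i in range(5)},
                         groups={f"v{i}": "Environment" for i in range(5)})
        return tbl

    def test_record_count_is_twice_the_pairs_tested(self, env_table):
        assocs = screen_all(env_table, ScreenConfig(n_perm=49, seed=0))
        assert len(assocs) == 2 * 10
        assert set(assocs["assoc_type"]) == {"Environment->Environment"}

    def test_same_seed_gives_identical_tables(self, env_table):
        cfg = ScreenConfig(n_perm=49, seed=11)
        a = screen_all(env_table, cfg).to_csv()
        b = screen_all(env_table, cfg).to_csv()
        assert a == b

    def test_point_estimates_do_not_depend_on_permutation_count(self, env_table):
        a = screen_all(env_table, ScreenConfig(n_perm=19, seed=5))
        b = screen_all(env_table, ScreenConfig(n_perm=99, seed=5))
        for col in ("q", "m", "a", "rho"):
            assert np.array_equal(a[col], b[col])

    def test_empty_variable_set_rejected(self):
        tbl = make_table({"c": np.ones(20)})
        with pytest.raises(ValueError, match="no variables"):
            screen_all(tbl, ScreenConfig())


def _assoc_frame(counts_by_type):
    """Edge-table stub with given {assoc_type: {klass: count}}."""
    rows = []
    for atype, classes in counts_by_type.items():
        for klass, k in classes.items():
            for i in range(k):
                rows.append({"source": "s", "target": "t", "assoc_type": atype,
                             "n_used": 20, "q": 0.5, "p_q": 0.01, "m": 0.0,
                             "a": 0.0, "rho": 0.0, "p_rho": 0.5, "klass": klass})
    return pd.DataFrame(rows)


class TestProportions:
    def test_equal_tables_give_zero_G(self):
        assocs = _assoc_frame({
            "A->A": {"positive": 10, "negative": 10, "non-monotonic": 10},
            "A->B": {"positive": 10, "negative": 10, "non-monotonic": 10},
        })
        props, gtests = proportions_by_type(assocs)
        assert np.allclose(props[[c for c in props if c.startswith("prop_")]], 1 / 3)
        assert gtests["G"].iloc[0] == pytest.approx(0.0)
        assert gtests["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_G_statistic(self):
        # 2x2 table [[20,5],[5,20]]: G = 2 * sum O ln(O/E) = 19.2745
        assocs = _assoc_frame({
            "A->A": {"positive": 20, "negative": 5},
            "A->B": {"positive": 5, "negative": 20},
        })
        _, gtests = proportions_by_type(assocs)
        assert gtests["G"].iloc[0] == pytest.approx(19.2745, abs=1e-4)

    def test_not_significant_records_are_excluded(self):
        assocs = _assoc_frame({"A->A": {"positive": 5, "not-significant": 50}})
        props, _ = proportions_by_type(assocs)
        assert props.loc["A->A", "n_significant"] == 5


class TestStages:
    def test_split_of_135_plots_is_68_67(self):
        tbl = make_table({"v": np.arange(135.0) + 1},
                         kinds={"v": "measurement"})
        early, late = split_stages(tbl)
        assert (early.n_plots, late.n_plots) == (68, 67)

    def test_identical_stages_give_p_one(self):
        assocs = _assoc_frame({
            "A->A": {"positive": 10, "non-monotonic": 5},
            "A->B": {"positive": 3, "non-monotonic": 7},
        })
        report = compare_stages(assocs, assocs.copy())
        assert np.allclose(report["p"], 1.0)

    def test_uniform_shift_reaches_exact_wilcoxon_floor(self):
        # +10% positive (and -10% non-monotonic) in every one of 12 types:
        # the two-sided exact signed-rank p for n = 12 is 2/2^12
        early = {f"T{i}->T{i}": {"positive": 40, "non-monotonic": 60}
                 for i in range(12)}
        late = {f"T{i}->T{i}": {"positive": 50, "non-monotonic": 50}
                for i in range(12)}
        report = compare_stages(_assoc_frame(early), _assoc_frame(late))
        p_pos = report.loc[report.klass == "positive", "p"].iloc[0]
        assert p_pos == pytest.approx(2 / 2**12)

    def test_single_shared_type_rejected(self):
        assocs = _assoc_frame({"A->A": {"positive": 5}})
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_stages(assocs, assocs)
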