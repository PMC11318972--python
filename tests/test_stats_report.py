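import itertools

import numpy as np
import pytest

from arbornet.errors import ValidationError
from arbornet.stats_report import (
    benjamini_hochberg,
    chi_square,
    ks_one_sided,
    mann_whitney,
    percent_reduction,
    run_pipeline,
    spearman,
)


def exact_ks_permutation_p(a, b, alternative):
    """Exhaustive permutation distribution of the one-sided two-sample KS
    statistic for small samples with distinct values."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def stat(x, y):
        grid = np.sort(pooled)
        fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        d = fy - fx if alternative == "less" else fx - fy
        return d.max()

    observed = stat(a, b)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        total += 1
        if stat(x, y) >= observed - 1e-12:
            count += 1
    return count / total


class TestKS:
    def test_identical_samples(self):
        r = ks_one_sided([1.0, 2, 3], [1.0, 2, 3], "less")
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1.0)

    def test_disjoint_supports_statistic_one(self):
        r = ks_one_sided([1.0, 2, 3], [4.0, 5, 6], "greater")
        assert r.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_small_sample_p_matches_permutation_enumeration(self, alternative):
        rng = np.random.default_rng(42)
        for _ in range(4):
            a = rng.normal(size=5)
            b = rng.normal(0.8, size=6)
            r = ks_one_sided(a, b, alternative)
            oracle = exact_ks_permutation_p(a, b, alternative)
            assert r.p_value == pytest.approx(oracle, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_one_sided([], [1.0], "less")


class TestChiSquare:
    def test_uniform_table_is_null(self):
        r = chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # expected counts all 30; chi2 = 4 * 20^2/30 = 53.33, df 1
        r = chi_square([[50, 10], [10, 50]])
        assert r.statistic == pytest.approx(160.0 / 3, rel=1e-12)
        assert "df=1" in r.detail

    def test_zero_column_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[5, 0], [7, 0]])


class TestSpearman:
    def test_monotone_is_one(self):
        r = spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert r.statistic == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        r = spearman([1, 2, 3, 4], [9, 7, 4, 1])
        assert r.statistic == pytest.approx(-1.0)

    def test_ties_match_average_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        r = spearman(x, y)
        assert r.statistic == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPercentReduction:
    def test_paper_style_worked_example(self):
        assert percent_reduction(0.87, 0.34) == 61

    def test_no_change(self):
        assert percent_reduction(1.0, 1.0) == 0

    def test_halving(self):
        assert percent_reduction(2.0, 1.0) == 50

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_reduction(0.0, 1.0)


class TestHelpers:
    def test_mann_whitney_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(2.0, size=30)
        assert mann_whitney(a, b).p_value < 1e-6

    def test_bh_monotone(self):
        p = [0.001, 0.02, 0.04, 0.9]
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


class TestNullCalibration:
    def test_matched_cohorts_do_not_inflate_false_positives(self):
        """Same-preset cohorts: occurrence chi-square rejects at ~alpha."""
        from arbornet.synthetic_data import preset_config, sample_feature_plan

        cfg = preset_config("control_like")
        alpha = 0.05
        rejections = 0
        n_rep = 60
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            tables = []
            for _arm in range(2):
                n_loop = n_term = 0
                for _ in range(20):
                    plan = sample_feature_plan(cfg, rng)
                    sel = (plan.lengths >= 10) & (plan.lengths < 30)
                    kinds = np.asarray(plan.kinds)[sel]
                    n_loop += int((kinds == "loop").sum())
                    n_term += int((kinds == "terminal").sum())
                tables.append([n_loop, n_term])
            r = chi_square(tables)
            rejections += r.p_value < alpha
        # binomial(60, 0.05): >= 9 rejections has probability < 0.002
        assert rejections <= 8


class TestPipeline:
    def test_synthetic_two_cohort_run(self, tmp_path):
        config = {
            "synthetic": {
                "cohorts": [
                    {"preset": "control_like", "n": 3, "seed_start": 0},
                    {"preset": "mutant_like", "n": 3, "seed_start": 100},
                ]
            },
            "params": {"ks_alternative": "less"},
        }
        out = run_pipeline(config, out_dir=tmp_path)
        assert out["report"]["n_neuromasts"] == 6
        assert set(out["metrics"]["genotype"]) == {"control_like", "mutant_like"}
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "tests.csv").exists()
        assert len(out["tests"]) > 0
        assert out["tests"]["p_value"].between(0, 1).all()

    def test_single_cohort_skips_tests(self):
        config = {
            "synthetic": {"cohorts": [{"preset": "control_like", "n": 2,
                                       "seed_start": 5}]},
        }
        out = run_pipeline(config)
        assert out["tests"].empty

    def test_file_inputs_and_missing_puncta(self, tmp_path):
        from arbornet.synthetic_data import generate_neuromast, preset_config
        from arbornet.trace_io import write_cluster_json, write_swc

        cluster, trace, puncta, _ = generate_neuromast(
            preset_config("control_like", seed=1)
        )
        write_swc(trace, tmp_path / "t.swc")
        write_cluster_json(cluster, tmp_path / "c.json")
        config = {
            "neuromasts": [
                {"id": "nm1", "trace": str(tmp_path / "t.swc"),
                 "cluster": str(tmp_path / "c.json"), "genotype": "control"},
            ]
        }
        out = run_pipeline(config)
        assert out["report"]["n_neuromasts"] == 1
        assert "puncta_on_loops" not in out["metrics"].columns
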