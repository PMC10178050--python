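import numpy as np
import pandas as pd
import pytest

from conftest import make_meta
from edikit.annotation import SiteAnnotation
from edikit.correlation import (
    correlate_adar,
    correlate_site_expression,
    correlated_site_enrichment,
    rpkm,
    summarize_correlations,
)
from test_differential import make_matrix


class TestRpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        lengths = pd.Series({"g1": 1000})
        out = rpkm(counts, lengths, library_sizes=pd.Series({"s1": 1_000_000}))
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        out = rpkm(counts, pd.Series({"g1": 500}), pd.Series({"s1": 1e6}))
        assert out.loc["g1", "s1"] == 0.0

    def test_doubling_library_halves_values(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        a = rpkm(counts, lengths, pd.Series({"s1": 1e6}))
        b = rpkm(counts, lengths, pd.Series({"s1": 2e6}))
        assert np.allclose(a.values, 2 * b.values)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s1": [1]}, index=["g1"]), pd.Series({"g1": 0}))


def eight_sample_meta():
    return make_meta(n_individuals=8, tissues=("Du",), hed=("P1", "P2", "P3", "P4"))


def expr_frame(values, gene="G1"):
    return pd.DataFrame({f"P{i + 1}_Du": [values[i]] for i in range(len(values))}, index=[gene])


def annotations_for(site_key, gene="G1", classes=("exon", "three_prime_utr")):
    return {site_key: SiteAnnotation(site_key, gene_ids=[gene], classes=set(classes))}


class TestCorrelateSiteExpression:
    def test_perfect_linear(self):
        meta = eight_sample_meta()[:5] if False else eight_sample_meta()
        levels = {"1:9:+": {f"P{i + 1}_Du": 0.1 * (i + 1) for i in range(5)}}
        matrix = make_matrix(levels, meta)
        expr = expr_frame([1, 2, 3, 4, 5, 0, 0, 0])
        (res,) = correlate_site_expression(matrix, expr, annotations_for("1:9:+"))
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 5
        assert res.strong and res.positive and res.significant

    def test_anti_linear(self):
        meta = eight_sample_meta()
        levels = {"1:9:+": {f"P{i + 1}_Du": 0.1 * (5 - i) for i in range(5)}}
        matrix = make_matrix(levels, meta)
        (res,) = correlate_site_expression(matrix, expr_frame([1, 2, 3, 4, 5, 9, 9, 9]), annotations_for("1:9:+"))
        assert res.r == pytest.approx(-1.0)
        assert not res.positive

    def test_strong_threshold_inclusive(self):
        # engineered vectors with r exactly 0.5
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(0.5)
        meta = eight_sample_meta()
        levels = {"1:9:+": {f"P{i + 1}_Du": 0.1 * x[i] for i in range(3)}}
        matrix = make_matrix(levels, meta)
        (res,) = correlate_site_expression(
            matrix, expr_frame(list(y) + [0] * 5), annotations_for("1:9:+"), min_pairs=3
        )
        assert res.strong is True

    def test_min_pairs_skip(self):
        meta = eight_sample_meta()
        levels = {"1:9:+": {"P1_Du": 0.1, "P2_Du": 0.5, "P3_Du": 0.3}}
        matrix = make_matrix(levels, meta)
        out = correlate_site_expression(matrix, expr_frame([1] * 8), annotations_for("1:9:+"), min_pairs=5)
        assert out == []

    def test_zero_variance_skip(self):
        meta = eight_sample_meta()
        levels = {"1:9:+": {f"P{i + 1}_Du": 0.4 for i in range(8)}}
        matrix = make_matrix(levels, meta)
        out = correlate_site_expression(matrix, expr_frame([3] * 8), annotations_for("1:9:+"), min_pairs=5)
        assert out == []

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        meta = eight_sample_meta()
        vals = rng.uniform(0.1, 0.9, 8)
        expr_vals = rng.uniform(1, 50, 8)
        levels = {"1:9:+": {f"P{i + 1}_Du": vals[i] for i in range(8)}}
        (res,) = correlate_site_expression(
            make_matrix(levels, meta), expr_frame(list(expr_vals)), annotations_for("1:9:+")
        )
        perm = rng.permutation(8)
        levels_p = {"1:9:+": {f"P{i + 1}_Du": vals[perm[i]] for i in range(8)}}
        (res_p,) = correlate_site_expression(
            make_matrix(levels_p, meta), expr_frame(list(expr_vals[perm])), annotations_for("1:9:+")
        )
        assert res_p.r == pytest.approx(res.r)

    def test_matches_two_pass_textbook_formula(self):
        rng = np.random.default_rng(123)
        meta = eight_sample_meta()
        for _ in range(20):
            vals = rng.uniform(0, 1, 8)
            expr_vals = rng.uniform(0, 100, 8)
            levels = {"1:9:+": {f"P{i + 1}_Du": vals[i] for i in range(8)}}
            (res,) = correlate_site_expression(
                make_matrix(levels, meta), expr_frame(list(expr_vals)), annotations_for("1:9:+")
            )
            xm, ym = vals - vals.mean(), expr_vals - expr_vals.mean()
            r_oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            assert res.r == pytest.approx(r_oracle, abs=1e-12)


class TestCorrelateAdar:
    def test_cardinality_bound_and_missing_id(self):
        meta = eight_sample_meta()
        rng = np.random.default_rng(5)
        levels = {
            f"1:{i}:+": {f"P{j + 1}_Du": float(rng.uniform(0.1, 0.9)) for j in range(8)}
            for i in range(4)
        }
        matrix = make_matrix(levels, meta)
        expr = pd.DataFrame(
            {f"P{i + 1}_Du": [rng.uniform(1, 9), rng.uniform(1, 9)] for i in range(8)},
            index=["ADAR", "ADARB1"],
        )
        out = correlate_adar(matrix, expr, ["ADAR", "ADARB1", "MISSING"])
        assert len(out) <= 3 * 4
        assert {r.feature_id for r in out} <= {"ADAR", "ADARB1"}

    def test_constant_adar_all_skipped(self):
        meta = eight_sample_meta()
        levels = {"1:1:+": {f"P{i + 1}_Du": 0.1 * (i + 1) for i in range(8)}}
        expr = pd.DataFrame({f"P{i + 1}_Du": [5.0] for i in range(8)}, index=["ADAR"])
        assert correlate_adar(make_matrix(levels, meta), expr, ["ADAR"]) == []

    def test_adar_driven_study_recovers_coupling(self, tmp_path):
        """When stable-site levels are coupled to ADAR expression, the
        median site-ADAR correlation is strongly positive."""
        from edikit.correlation import rpkm as _rpkm
        from edikit.io_formats import read_expression
        from edikit.pipeline import run_pipeline
        from edikit.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(seed=31, adar_coupling=1.0, n_sites=150, n_differential=0,
                               n_hed_specific=0, n_nd_specific=0, n_recoding=0, n_correlated=0)
        study = simulate_study(cfg, tmp_path / "adar_study")
        res = run_pipeline(study.out_dir)
        counts, lengths = read_expression(study.gene_counts)
        expr = _rpkm(counts, lengths)
        out = correlate_adar(res.matrix, expr, ["ADAR"])
        rs = [r.r for r in out]
        assert np.median(rs) > 0.5


def test_null_pairs_flagged_at_alpha_rate():
    """Uncorrelated site/expression pairs reach p < 0.05 at about the
    nominal rate (within 3 s.e. over 1000 null pairs)."""
    rng = np.random.default_rng(2718)
    meta = make_meta(n_individuals=8, tissues=("Du", "Li"), hed=("P1", "P2", "P3", "P4"))
    samples = [m.sample_id for m in meta]  # 16 samples
    n_pairs, alpha = 1000, 0.05
    levels = {
        f"1:{i}:+": dict(zip(samples, rng.uniform(0.05, 0.95, len(samples))))
        for i in range(n_pairs)
    }
    matrix = make_matrix(levels, meta)
    expr = pd.DataFrame({s: [rng.uniform(1, 100)] for s in samples}, index=["G1"])
    anns = {k: SiteAnnotation(k, gene_ids=["G1"], classes={"exon"}) for k in levels}
    results = correlate_site_expression(matrix, expr, anns)
    assert len(results) == n_pairs
    rate = np.mean([r.significant for r in results])
    se = np.sqrt(alpha * (1 - alpha) / n_pairs)
    assert abs(rate - alpha) < 3 * se


class TestEnrichmentDelegation:
    def test_equal_proportions_not_significant(self):
        anns = {}
        all_sites = set()
        for i in range(100):
            k = f"1:{i}:+"
            all_sites.add(k)
            anns[k] = SiteAnnotation(k, classes={"three_prime_utr"} if i < 50 else {"intron"})
        correlated = {f"1:{i}:+" for i in list(range(0, 10)) + list(range(50, 60))}
        results = correlated_site_enrichment(correlated, all_sites, anns)
        utr = next(r for r in results if r.category == "three_prime_utr")
        assert utr.fold == pytest.approx(1.0)
        assert not utr.significant

    def test_empty_correlated_set(self):
        assert correlated_site_enrichment(set(), {"1:1:+"}, {}) == []


def test_summary_counts(pipeline_result, study):
    summary = summarize_correlations(pipeline_result.correlations, pipeline_result.matrix.n_sites)
    assert summary["n_sites_significant"] >= len(study.truth.by_class("expression_correlated"))
    assert 0 <= summary["pct_sites_significant"] <= 100
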