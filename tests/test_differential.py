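from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import make_meta
from edikit.differential import (
    assemble_functional_sites,
    classify_treatment_specific,
    per_site_test,
    run_pca,
    tissue_level_test,
    wilcoxon_rank_sum,
)
from edikit.filtering import EditingMatrix, metadata_frame


def rank_sum_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in combinations(range(n + m), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def make_matrix(levels: dict, meta):
    """levels: site_key -> {sample_id: level}; missing samples are NaN."""
    mdf = metadata_frame(meta)
    data = pd.DataFrame(
        {s: {k: v.get(s, np.nan) for k, v in levels.items()} for s in mdf.index}
    )
    data = data.reindex(index=list(levels))
    sites = pd.DataFrame(
        {
            "chrom": [k.split(":")[0] for k in levels],
            "pos": [int(k.split(":")[1]) for k in levels],
            "strand": [k.split(":")[2] for k in levels],
            "substitution": ["AG"] * len(levels),
        },
        index=pd.Index(list(levels), name="site_key"),
    )
    return EditingMatrix(data, sites, mdf)


class TestWilcoxonRankSum:
    def test_fully_separated_4v4(self):
        p = wilcoxon_rank_sum([0.9, 0.8, 0.85, 0.95], [0.1, 0.2, 0.15, 0.12])
        assert p == pytest.approx(2 / 70)

    def test_fully_separated_3v3_cannot_reach_005(self):
        p = wilcoxon_rank_sum([0.9, 0.8, 0.85], [0.1, 0.2, 0.15])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        p = wilcoxon_rank_sum([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert p == pytest.approx(1.0)

    def test_20v20_full_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.6, 0.9, 20)
        y = rng.uniform(0.1, 0.4, 20)
        assert wilcoxon_rank_sum(x, y) < 1e-3

    def test_exact_matches_enumeration_small_sizes(self):
        rng = np.random.default_rng(42)
        for n in (2, 3, 4):
            for m in (2, 3, 4):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                assert wilcoxon_rank_sum(x, y) == pytest.approx(
                    rank_sum_enumeration_oracle(x, y)
                ), (n, m)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestRunPca:
    def test_rank_one_data(self):
        meta = make_meta(n_individuals=2, tissues=("Du", "Li"))
        base = {"P1_Du": 0.1, "P1_Li": 0.2, "P2_Du": 0.3, "P2_Li": 0.4}
        levels = {
            f"1:{i}:+": {s: v * (i + 1) / 5 for s, v in base.items()} for i in range(5)
        }
        res = run_pca(make_matrix(levels, meta))
        assert res.explained_sd_ratio[0] == pytest.approx(1.0)

    def test_sd_ratio_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        meta = make_meta(n_individuals=2, tissues=("Du", "Li"))
        samples = [m.sample_id for m in meta]
        X = rng.uniform(0, 1, size=(3, 4))  # 3 sites x 4 samples
        levels = {f"1:{i}:+": dict(zip(samples, X[i])) for i in range(3)}
        res = run_pca(make_matrix(levels, meta))
        cov = np.cov(X.T, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
        sd = np.sqrt(eig[: len(res.sdev)])
        expected = sd / sd.sum()
        assert np.allclose(res.explained_sd_ratio, expected, atol=1e-9)

    def test_duplicated_samples_identical_scores(self):
        meta = make_meta(n_individuals=2, tissues=("Du", "Li"))
        levels = {
            "1:1:+": {"P1_Du": 0.2, "P1_Li": 0.2, "P2_Du": 0.7, "P2_Li": 0.7},
            "1:2:+": {"P1_Du": 0.5, "P1_Li": 0.5, "P2_Du": 0.1, "P2_Li": 0.1},
        }
        res = run_pca(make_matrix(levels, meta))
        assert np.allclose(res.scores.loc["P1_Du"], res.scores.loc["P1_Li"])

    def test_explained_fractions_sum_to_one(self, pipeline_result):
        total = pipeline_result.pca.explained_sd_ratio.sum()
        assert total == pytest.approx(1.0)

    def test_fewer_than_two_samples_errors(self):
        meta = make_meta(n_individuals=1, tissues=("Du",))
        levels = {"1:1:+": {"P1_Du": 0.2}}
        with pytest.raises(ValueError):
            run_pca(make_matrix(levels, meta))


class TestTissueLevelTest:
    def test_identical_distributions(self):
        meta = make_meta()
        levels = {f"1:{i}:+": {m.sample_id: 0.1 * (i + 1) for m in meta if m.tissue == "Du"} for i in range(4)}
        res = tissue_level_test(make_matrix(levels, meta), "Du")
        assert res["p_value"] == pytest.approx(1.0)

    def test_relative_change_arithmetic(self):
        # mean_nd 0.298, mean_hed 0.314 -> +5.4 %
        assert (0.314 - 0.298) / 0.298 == pytest.approx(0.0537, abs=1e-4)
        meta = make_meta(n_individuals=2, tissues=("Du",), hed=("P1",))
        levels = {"1:1:+": {"P1_Du": 0.314, "P2_Du": 0.298}}
        res = tissue_level_test(make_matrix(levels, meta), "Du")
        assert res["relative_change"] == pytest.approx((0.314 - 0.298) / 0.298)

    def test_missing_treatment_errors(self):
        meta = make_meta(hed=("P1", "P2", "P3", "P4"))  # all HED
        levels = {"1:1:+": {m.sample_id: 0.5 for m in meta}}
        with pytest.raises(ValueError):
            tissue_level_test(make_matrix(levels, meta), "Du")


class TestPerSiteTest:
    def make_8sample_meta(self):
        return make_meta(n_individuals=8, tissues=("Du",), hed=("P1", "P2", "P3", "P4"))

    def test_separated_4v4_significant_with_direction(self):
        meta = self.make_8sample_meta()
        levels = {
            "1:1:+": {
                "P1_Du": 0.9, "P2_Du": 0.8, "P3_Du": 0.85, "P4_Du": 0.95,
                "P5_Du": 0.1, "P6_Du": 0.2, "P7_Du": 0.15, "P8_Du": 0.12,
            }
        }
        (res,) = per_site_test(make_matrix(levels, meta), "Du")
        assert res.klass == "differential"
        assert res.p_value == pytest.approx(2 / 70)
        assert res.direction == "higher"

    def test_3v3_separated_not_significant_exact(self):
        meta = self.make_8sample_meta()
        levels = {
            "1:1:+": {
                "P1_Du": 0.9, "P2_Du": 0.8, "P3_Du": 0.85,
                "P5_Du": 0.1, "P6_Du": 0.2, "P7_Du": 0.15,
            }
        }
        (res,) = per_site_test(make_matrix(levels, meta), "Du")
        assert res.p_value == pytest.approx(0.1)
        assert res.klass == "not-significant"

    def test_below_group_minimum_not_testable(self):
        meta = self.make_8sample_meta()
        levels = {"1:1:+": {"P1_Du": 0.9, "P2_Du": 0.8, "P5_Du": 0.1}}
        (res,) = per_site_test(make_matrix(levels, meta), "Du")
        assert res.klass == "not-testable"
        assert res.p_value is None


class TestTreatmentSpecific:
    def make_levels(self, hed_detect, nd_detect):
        meta = make_meta(n_individuals=8, tissues=("Du",), hed=("P1", "P2", "P3", "P4"))
        hed_ids = [f"P{i}_Du" for i in range(1, 5)][:hed_detect]
        nd_ids = [f"P{i}_Du" for i in range(5, 9)][:nd_detect]
        levels = {"1:1:+": {s: 0.4 for s in hed_ids + nd_ids}}
        return make_matrix(levels, meta)

    @pytest.mark.parametrize(
        "hed,nd,expected",
        [(3, 0, "HED-specific"), (4, 1, None), (2, 0, None), (0, 3, "ND-specific")],
    )
    def test_definition(self, hed, nd, expected):
        out = classify_treatment_specific(self.make_levels(hed, nd), "Du")
        if expected is None:
            assert out == []
        else:
            assert out[0].klass == expected

    def test_specific_sites_are_untestable(self, pipeline_result):
        """A treatment-specific site has zero detections in one arm, so the
        per-site test can never have run on it in that tissue."""
        tested = {
            (r.site_key, r.tissue)
            for r in pipeline_result.diff_results
            if r.klass in ("differential", "not-significant")
        }
        specific = {(r.site_key, r.tissue) for r in pipeline_result.specific_results}
        assert not (tested & specific)


class TestAssembleFunctional:
    def test_counts_and_pooled_non_redundancy(self):
        from edikit.differential import DiffResult

        spec = [
            DiffResult("s1", "Du", 3, 0, None, None, "HED-specific"),
            DiffResult("s2", "Du", 4, 0, None, None, "HED-specific"),
            DiffResult("s1", "Li", 3, 0, None, None, "HED-specific"),
        ]
        diff = [DiffResult("s3", "Du", 4, 4, 0.02, "higher", "differential")]
        fs = assemble_functional_sites(diff, spec)
        assert fs.per_tissue.loc["Du", "Spe/Dif"] == 3
        assert fs.per_tissue.loc["Du", "HED"] == 2
        assert fs.per_tissue.loc["Du", "Higher"] == 1
        assert len(fs.pooled) == 3  # s1 counted once despite two tissues

    def test_empty_inputs(self):
        fs = assemble_functional_sites([], [])
        assert fs.pooled == set()
        assert fs.per_tissue.empty
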