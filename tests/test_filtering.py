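import numpy as np
import pytest

from conftest import make_meta
from edikit.filtering import (
    CandidateSite,
    apply_filtration,
    select_candidates,
    subset_atoi,
)
from edikit.io_formats import BaseCall


def rna_call(pos=100, cov=20, var=6, sub="AG", chrom="1", strand="+"):
    counts = [0, 0, 0, 0]
    counts[{"A": 0, "C": 1, "G": 2, "T": 3}[sub[0]]] = cov - var
    counts[{"A": 0, "C": 1, "G": 2, "T": 3}[sub[1]]] = var
    return BaseCall(chrom, pos, strand, sub[0], tuple(counts), cov, sub, var / cov)


def dna_call(pos=100, cov=30, ref="A", alt_reads=0, alt="G", chrom="1"):
    counts = [0, 0, 0, 0]
    counts[{"A": 0, "C": 1, "G": 2, "T": 3}[ref]] = cov - alt_reads
    counts[{"A": 0, "C": 1, "G": 2, "T": 3}[alt]] = alt_reads
    return BaseCall(chrom, pos, "unknown", ref, tuple(counts), cov, "-", 0.0)


class TestSelectCandidates:
    def test_all_thresholds_met(self):
        out = select_candidates([rna_call(cov=20, var=6)], [dna_call(cov=30)])
        assert len(out) == 1
        assert out[0].level == pytest.approx(0.30)

    def test_insufficient_variant_reads(self):
        assert select_candidates([rna_call(cov=20, var=4)], [dna_call()]) == []

    def test_dna_non_variation_below_095(self):
        # 27/30 reference reads = 0.90 < 0.95
        assert select_candidates([rna_call()], [dna_call(cov=30, alt_reads=3)]) == []
        # 29/30 = 0.967 passes
        assert len(select_candidates([rna_call()], [dna_call(cov=30, alt_reads=1)])) == 1

    def test_no_dna_record_excluded_not_error(self):
        assert select_candidates([rna_call(pos=5)], [dna_call(pos=100)]) == []

    def test_low_coverage_dropped(self):
        assert select_candidates([rna_call(cov=4, var=4)], [dna_call()]) == []
        assert select_candidates([rna_call()], [dna_call(cov=4)]) == []

    def test_multiple_substitutions_excluded(self):
        bad = BaseCall("1", 7, "+", "A", (10, 0, 5, 5), 20, "AG CT", 0.25)
        assert select_candidates([bad], [dna_call(pos=7)]) == []


def candidates_fixture():
    """6 samples (3 individuals x 2 tissues), hand-built candidate sets."""
    meta = make_meta(n_individuals=4, tissues=("Du", "Li"), hed=("P1", "P2"))

    def c(pos, level=0.3, strand="+", sub="AG", chrom="1"):
        return CandidateSite(chrom, pos, strand, sub, level)

    everywhere = [c(10), c(20, sub="CT"), c(30)]
    candidates = {m.sample_id: list(everywhere) for m in meta}
    # site 40: only 2 samples of Du -> removed by step 3
    candidates["P1_Du"].append(c(40))
    candidates["P2_Du"].append(c(40))
    # site 50: fully edited everywhere
    for m in meta:
        candidates[m.sample_id].append(c(50, level=1.0))
    # site 60: level 1.0 in some but not all samples -> kept
    for m in meta:
        candidates[m.sample_id].append(c(60, level=1.0 if m.tissue == "Du" else 0.8))
    # site 70: known SNP; site 80: individual variant; site 90: on chrX
    for m in meta:
        candidates[m.sample_id].extend([c(70), c(80), c(90, chrom="X")])
    known = {("1", 70, "SNP")}
    indiv = {"P3": {("1", 80, "INDEL")}}
    return candidates, known, indiv, meta


class TestApplyFiltration:
    def test_cascade(self):
        candidates, known, indiv, meta = candidates_fixture()
        m = apply_filtration(candidates, known, indiv, meta, min_samples=3, autosomes=["1"])
        keys = set(m.levels.index)
        assert keys == {"1:10:+", "1:20:+", "1:30:+", "1:60:+"}

    def test_known_snp_removed_despite_wide_detection(self):
        candidates, known, indiv, meta = candidates_fixture()
        m = apply_filtration(candidates, known, indiv, meta, autosomes=["1"])
        assert "1:70:+" not in m.levels.index

    def test_three_samples_one_tissue_kept(self):
        candidates, known, indiv, meta = candidates_fixture()
        only3 = {k: [] for k in candidates}
        for s in ("P1_Du", "P2_Du", "P3_Du"):
            only3[s] = [CandidateSite("1", 11, "+", "AG", 0.4)]
        m = apply_filtration(only3, set(), {}, meta, min_samples=3, autosomes=["1"])
        assert list(m.levels.index) == ["1:11:+"]

    def test_full_edit_removed_partial_kept(self):
        candidates, known, indiv, meta = candidates_fixture()
        m = apply_filtration(candidates, known, indiv, meta, autosomes=["1"])
        assert "1:50:+" not in m.levels.index
        assert "1:60:+" in m.levels.index

    def test_per_individual_masking(self):
        candidates, known, indiv, meta = candidates_fixture()
        m = apply_filtration(candidates, known, indiv, meta, autosomes=["1"], per_individual=True)
        # P3 carries the variant at 80: only its samples are masked
        assert "1:80:+" in m.levels.index
        row = m.levels.loc["1:80:+"]
        assert np.isnan(row["P3_Du"]) and np.isnan(row["P3_Li"])
        assert not np.isnan(row["P1_Du"])

    def test_unknown_sample_errors(self):
        candidates, known, indiv, meta = candidates_fixture()
        candidates["mystery"] = []
        with pytest.raises(ValueError, match="mystery"):
            apply_filtration(candidates, known, indiv, meta)

    def test_min_samples_monotonicity(self):
        candidates, known, indiv, meta = candidates_fixture()
        sizes = [
            apply_filtration(candidates, known, indiv, meta, min_samples=k, autosomes=["1"]).n_sites
            for k in (1, 2, 3, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_input_order_invariance(self):
        candidates, known, indiv, meta = candidates_fixture()
        ref = apply_filtration(candidates, known, indiv, meta, autosomes=["1"])
        shuffled = {k: list(reversed(v)) for k, v in reversed(candidates.items())}
        alt = apply_filtration(shuffled, known, indiv, meta, autosomes=["1"])
        assert list(ref.levels.index) == list(alt.levels.index)


class TestSubsetAtoi:
    def test_definition_empty_and_idempotence(self):
        candidates, known, indiv, meta = candidates_fixture()
        m = apply_filtration(candidates, known, indiv, meta, autosomes=["1"])
        atoi = subset_atoi(m)
        assert set(atoi.sites["substitution"]) == {"AG"}
        assert "1:20:+" not in atoi.levels.index
        again = subset_atoi(atoi)
        assert list(again.levels.index) == list(atoi.levels.index)
        empty = subset_atoi(atoi.subset_sites([]))
        assert empty.n_sites == 0


def brute_force_filter(candidates, known, indiv, meta, min_samples, autosomes):
    """Independent nested-loop re-statement of the cascade."""
    all_sites = {}
    for sample, sites in candidates.items():
        for c in sites:
            all_sites.setdefault((c.chrom, c.pos, c.strand), set()).add(sample)
    known_pos = {(c, p) for c, p, _ in known}
    var_pos = {(c, p) for s in indiv.values() for c, p, _ in s}
    tissue = {m.sample_id: m.tissue for m in meta}
    surviving = []
    for (chrom, pos, strand), samples in all_sites.items():
        if strand == "unknown" or chrom not in autosomes:
            continue
        if (chrom, pos) in known_pos or (chrom, pos) in var_pos:
            continue
        ok3 = False
        for t in {tissue[s] for s in samples}:
            if sum(1 for s in samples if tissue[s] == t) >= min_samples:
                ok3 = True
        if not ok3:
            continue
        levels = [
            c.level
            for s in samples
            for c in candidates[s]
            if (c.chrom, c.pos, c.strand) == (chrom, pos, strand)
        ]
        if all(lv == 1.0 for lv in levels):
            continue
        surviving.append(f"{chrom}:{pos}:{strand}")
    return set(surviving)


def test_filtration_matches_bruteforce_oracle_small_random():
    rng = np.random.default_rng(5)
    meta = make_meta(n_individuals=4, tissues=("Du", "Li"), hed=("P1", "P2"))
    for _trial in range(5):
        candidates = {m.sample_id: [] for m in meta}
        positions = rng.choice(np.arange(10, 2000), size=50, replace=False)
        known, indiv = set(), {"P1": set()}
        for pos in positions:
            chrom = "1" if rng.random() < 0.9 else "X"
            level = 1.0 if rng.random() < 0.1 else float(rng.uniform(0.1, 0.9))
            detected = [m.sample_id for m in meta if rng.random() < 0.6]
            for s in detected:
                candidates[s].append(CandidateSite(chrom, int(pos), "+", "AG", level))
            if rng.random() < 0.1:
                known.add((chrom, int(pos), "SNP"))
            elif rng.random() < 0.1:
                indiv["P1"].add((chrom, int(pos), "SNP"))
        got = apply_filtration(candidates, known, indiv, meta, min_samples=3, autosomes=["1"])
        expected = brute_force_filter(candidates, known, indiv, meta, 3, {"1"})
        assert set(got.levels.index) == expected


def test_matrix_round_trip(tmp_path, pipeline_result):
    from edikit.filtering import EditingMatrix

    m = pipeline_result.matrix
    p = tmp_path / "matrix.tsv"
    m.write(p)
    m2 = EditingMatrix.read(p, m.meta)
    assert list(m2.levels.index) == list(m.levels.index)
    assert np.allclose(m2.levels.to_numpy(), m.levels.to_numpy(), equal_nan=True)
    assert (m2.sites["substitution"] == m.sites["substitution"]).all()
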