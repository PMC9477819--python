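from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pavpan.config import Thresholds
from pavpan.pav import DepthTrack, GeneModel, PAVMatrix, SampleMeta, build_pav_matrix
from pavpan.pop_compare import (
    absence_table,
    bh_fdr,
    compare_cohorts,
    fisher_exact_two_sided,
    hag_lag,
    odds_ratio,
    phenotype_association,
)
from pavpan.synthetic_data import simulate_presence_matrix


def _enumeration_oracle(a, b, c, d):
    """Independent exact oracle: per-table hypergeometric pmf as a
    Fraction, summed over tables no more probable than the observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    den = comb(n, c1)
    pmfs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), den)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = pmfs[a]
    return float(sum(p for p in pmfs.values() if p <= obs))


class TestFisher:
    def test_frozen_examples(self):
        # (5,0,0,5): only the two extreme tables qualify -> 2/252
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-15)
        # modal symmetric table
        assert fisher_exact_two_sided(2, 3, 2, 3) == 1.0

    def test_row_swap_symmetry(self):
        for a, b, c, d in [(3, 7, 1, 9), (0, 5, 4, 6), (2, 2, 8, 1)]:
            assert fisher_exact_two_sided(a, b, c, d) == fisher_exact_two_sided(c, d, a, b)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            _enumeration_oracle(a, b, c, d), abs=1e-12
        )

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_cross_check_against_scipy(self, a, b, c, d):
        _, p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(p_scipy, abs=1e-7)


class TestBH:
    def test_frozen_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.5]) == [0.5]
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_vector(self):
        # p sorted: .005 .01 .04 .5; q_(i) = min over j>=i of m p_(j)/j
        p = [0.04, 0.005, 0.5, 0.01]
        expected = [0.05333333, 0.02, 0.5, 0.02]
        assert bh_fdr(p) == pytest.approx(expected, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=25))
    def test_monotone_in_p_rank(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert all(
            q[order[i]] <= q[order[i + 1]] + 1e-12 for i in range(len(order) - 1)
        )
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, pvals))

    def test_step_up_rejection_set(self):
        """Flags at alpha reproduce the classic step-up rejection set."""
        pvals = [0.001, 0.008, 0.039, 0.041, 0.9]
        q = bh_fdr(pvals)
        m = len(pvals)
        ranked = sorted(enumerate(pvals), key=lambda x: x[1])
        kmax = max(
            (i + 1 for i, (_, p) in enumerate(ranked) if p <= 0.05 * (i + 1) / m),
            default=0,
        )
        stepup = {idx for idx, _ in ranked[:kmax]}
        assert {i for i, qi in enumerate(q) if qi < 0.05} == stepup


class TestOddsRatio:
    def test_direct_arithmetic(self):
        assert odds_ratio(10, 10, 5, 15) == pytest.approx(3.0)
        assert odds_ratio(5, 5, 5, 5) == 1.0

    def test_haldane_correction_on_zero_cell(self):
        assert odds_ratio(5, 0, 0, 5) == pytest.approx(121.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20), st.integers(1, 20))
    def test_inverse_invariance_without_correction(self, a, b, c, d):
        assert odds_ratio(a, b, c, d) * odds_ratio(b, a, d, c) == pytest.approx(1.0)


def _matrix_from_presence(presence_rows, gene_ids, cohort, host="chr1"):
    import pandas as pd

    samples = [f"{cohort}{i}" for i in range(len(presence_rows))]
    cov = pd.DataFrame(
        [[1.0 if v else 0.0 for v in row] for row in presence_rows],
        index=samples,
        columns=gene_ids,
    )
    genes = {
        g: GeneModel(gene_id=g, host=host, strand="+", transcripts=(((0, 100),),))
        for g in gene_ids
    }
    meta = {s: SampleMeta(s, cohort, "male") for s in samples}
    return PAVMatrix(coverage=cov, presence=cov > 0.8, genes=genes, meta=meta)


class TestAbsenceTable:
    def test_simple_counting(self):
        case = _matrix_from_presence([[0]] * 3 + [[1]] * 7, ["g"], "case")
        ctrl = _matrix_from_presence([[1]] * 10, ["g"], "ctrl")
        assert absence_table(case, ctrl, "g") == (3, 7, 0, 10)

    def test_missing_gene_names_it(self):
        case = _matrix_from_presence([[1]], ["g"], "case")
        ctrl = _matrix_from_presence([[1]], ["h"], "ctrl")
        with pytest.raises(KeyError, match="g"):
            absence_table(case, ctrl, "g")

    def test_identical_matrices_equal_freqs(self):
        m = _matrix_from_presence([[0], [1], [1], [0]], ["g"], "case")
        a, b, c, d = absence_table(m, m, "g")
        assert a / (a + b) == c / (c + d)


class TestCompareCohorts:
    def test_empty_intersection(self, thresholds):
        case = _matrix_from_presence([[1]], ["g1"], "case")
        ctrl = _matrix_from_presence([[1]], ["g2"], "ctrl")
        assert compare_cohorts(case, ctrl, thresholds) == []

    def test_planted_difference_flagged(self, thresholds):
        rng = np.random.default_rng(3)
        case_f = {f"g{i}": (0.6 if i < 5 else 0.2) for i in range(20)}
        ctrl_f = {f"g{i}": (0.05 if i < 5 else 0.2) for i in range(20)}
        mc, mx = simulate_presence_matrix(case_f, ctrl_f, 50, 50, rng)
        res = {r.gene_id: r for r in compare_cohorts(mc, mx, thresholds)}
        assert all(res[f"g{i}"].flagged for i in range(5))
        assert all(res[f"g{i}"].or_value > 1.5 for i in range(5))

    def test_sorted_by_q_then_gene(self, thresholds):
        rng = np.random.default_rng(4)
        mc, mx = simulate_presence_matrix(
            {"a": 0.7, "b": 0.2}, {"a": 0.05, "b": 0.2}, 40, 40, rng
        )
        res = compare_cohorts(mc, mx, thresholds)
        assert [r.q for r in res] == sorted(r.q for r in res)


class TestHagLag:
    def _matrix_with_coverages(self, cov_by_gene, n=10):
        import pandas as pd

        gene_ids = sorted(cov_by_gene)
        rows = {f"s{i}": [cov_by_gene[g] for g in gene_ids] for i in range(n)}
        cov = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
        genes = {
            g: GeneModel(gene_id=g, host="chr1", strand="+", transcripts=(((0, 100),),))
            for g in gene_ids
        }
        meta = {s: SampleMeta(s, "case", "male") for s in rows}
        return PAVMatrix(coverage=cov, presence=cov > 0.8, genes=genes, meta=meta)

    def test_low_coverage_absences_are_hag(self, thresholds):
        m = self._matrix_with_coverages({"g_lo": 0.1, "g_hi": 0.7})
        ctrl = self._matrix_with_coverages({"g_lo": 1.0, "g_hi": 1.0})
        comp = compare_cohorts(m, ctrl, thresholds)
        cat = hag_lag(m, comp, thresholds, top_n=20)
        assert cat.categories["g_lo"] == "HAG"
        assert cat.categories["g_hi"] == "LAG"

    def test_fewer_than_top_n(self, thresholds):
        m = self._matrix_with_coverages({"g": 0.1})
        ctrl = self._matrix_with_coverages({"g": 1.0})
        cat = hag_lag(m, compare_cohorts(m, ctrl, thresholds), thresholds, top_n=20)
        assert list(cat.categories) == ["g"]
        assert cat.ranks["g"] == 1


class TestPhenotype:
    def _matrix(self):
        genes = [
            GeneModel("g1", "chr1", "+", (((100, 700),),)),
            GeneModel("gy", "chrY", "+", (((100, 700),),)),
        ]
        tracks, meta = {}, []
        for i in range(8):
            sex = "male" if i % 2 == 0 else "female"
            t = DepthTrack()
            t.add("chr1", [(0, 1000)])
            if sex == "male":
                t.add("chrY", [(0, 1000)])
            tracks[f"s{i}"] = t
            meta.append(SampleMeta(f"s{i}", "case", sex, (("grade", "low" if i < 4 else "high"),)))
        return build_pav_matrix(genes, tracks, meta, Thresholds()), meta

    def test_single_level_is_error(self, thresholds):
        m, meta = self._matrix()
        flat = [SampleMeta(x.sample_id, x.cohort, x.sex, (("grade", "one"),)) for x in meta]
        with pytest.raises(ValueError, match="two levels"):
            phenotype_association(m, flat, "grade", thresholds)

    def test_sex_phenotype_excludes_chry(self, thresholds):
        m, meta = self._matrix()
        res = phenotype_association(m, meta, "sex", thresholds)
        assert {r.gene_id for r in res} == {"g1"}

    def test_null_phenotype_is_unflagged(self, thresholds):
        m, meta = self._matrix()
        res = phenotype_association(m, meta, "grade", thresholds)
        assert not any(r.flagged for r in res)
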