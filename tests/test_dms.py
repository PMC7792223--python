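import numpy as np
import pytest
from scipy import stats
from scipy.special import xlogy

from crossmeth.dms import classify_tissue_generality
from crossmeth.dms import test_pairwise_contrast as pairwise_contrast
from crossmeth.dms import test_time_omnibus as time_omnibus
from crossmeth.types import ContrastSpec, GenomicSite, MethylationCountTable, SampleMeta, ValidationError

from conftest import make_table

D12 = ContrastSpec.delta12()


def two_group_table(meth_a, cov_a, meth_b, cov_b):
    """One site, one sample per group (so the dispersion factor is 1)."""
    return make_table([[cov_a, cov_b]], [[meth_a, meth_b]], times=(1, 2))


def grid_lrt(meth_a, cov_a, meth_b, cov_b):
    """Independent oracle: maximize binomial likelihoods over a dense grid."""
    grid = np.arange(1, 10_000) / 10_000.0

    def best(m, n):
        return (xlogy(m, grid) + xlogy(n - m, 1 - grid)).max()

    ll_alt = best(meth_a, cov_a) + best(meth_b, cov_b)
    ll_null = (
        xlogy(meth_a + meth_b, grid) + xlogy(cov_a + cov_b - meth_a - meth_b, 1 - grid)
    ).max()
    return 2 * (ll_alt - ll_null)


class TestPairwiseContrast:
    def test_worked_example_pooled_counts(self):
        rec = pairwise_contrast(two_group_table(6, 60, 30, 60), D12)[0]
        assert rec.meth_diff == pytest.approx(40.0)
        assert rec.lrt_stat == pytest.approx(24.42, abs=0.01)
        assert rec.df == 1

    def test_identical_groups_null(self):
        rec = pairwise_contrast(two_group_table(5, 20, 5, 20), D12)[0]
        assert rec.lrt_stat == 0.0
        assert rec.p == 1.0

    def test_diff_below_threshold_not_dms_despite_tiny_q(self):
        rec = pairwise_contrast(two_group_table(0, 1000, 149, 1000), D12)[0]
        assert rec.meth_diff == pytest.approx(14.9)
        assert rec.q < 0.001
        assert not rec.is_dms

    def test_hypermethylation_at_later_time_is_positive(self):
        rec = pairwise_contrast(two_group_table(2, 30, 20, 30), D12)[0]
        assert rec.meth_diff > 0

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            cov_a, cov_b = rng.integers(5, 50, size=2)
            meth_a = rng.integers(1, cov_a)
            meth_b = rng.integers(1, cov_b)
            rec = pairwise_contrast(
                two_group_table(meth_a, cov_a, meth_b, cov_b),
                D12,
                overdispersion_correction=False,
            )[0]
            assert rec.lrt_stat == pytest.approx(
                grid_lrt(meth_a, cov_a, meth_b, cov_b), abs=1e-4
            )

    def test_dms_count_monotone_in_thresholds(self, rng):
        cov = rng.integers(10, 40, size=(300, 8))
        meth = rng.binomial(cov, rng.uniform(0.1, 0.9, size=(300, 1)))
        table = make_table(cov, meth, n_per_time=4)
        counts = []
        for diff, q in [(5, 0.05), (15, 0.05), (15, 0.01), (30, 0.001)]:
            recs = pairwise_contrast(table, D12, diff, q)
            counts.append(sum(r.is_dms for r in recs))
        assert counts == sorted(counts, reverse=True)

    def test_zero_coverage_group_skipped(self, caplog):
        table = make_table([[0, 10], [10, 10]], [[0, 5], [5, 5]], times=(1, 2))
        with caplog.at_level("WARNING"):
            recs = pairwise_contrast(table, D12)
        assert len(recs) == 1
        assert recs[0].site.pos == 110

    def test_requires_samples_in_both_groups(self):
        table = make_table([[10, 10]], [[5, 5]], times=(1, 1))
        with pytest.raises(ValidationError):
            pairwise_contrast(table, D12)


def omnibus_table(p_by_time, coverage=30, n_per_time=6, rng=None, temp_pp=0.0):
    samples, cov, meth = [], [], []
    for t in (1, 2, 3):
        for j in range(n_per_time):
            warm = j < n_per_time // 2
            p = np.clip(p_by_time[t - 1] + (temp_pp / 100 if warm else 0.0), 0.01, 0.99)
            samples.append(
                SampleMeta(f"s{t}{j}", f"f{t}{j}", "RBC", t, "warm" if warm else "cold")
            )
            cov.append(coverage)
            meth.append(rng.binomial(coverage, p) if rng is not None else round(coverage * p))
    return MethylationCountTable(
        [GenomicSite("chr1", 1, "+")], samples, np.array([cov]), np.array([meth])
    )


class TestOmnibus:
    def test_no_time_variation_gives_null(self):
        table = omnibus_table([0.4, 0.4, 0.4], temp_pp=20.0)
        rec = time_omnibus(table)[0]
        assert rec.lrt_stat == pytest.approx(0.0, abs=1e-5)
        assert rec.p == pytest.approx(1.0, abs=1e-4)
        assert rec.df == 2

    def test_strong_time_trend_detected_in_most_replicates(self, rng):
        hits = 0
        for _ in range(100):
            table = omnibus_table([0.2, 0.5, 0.8], rng=rng)
            hits += time_omnibus(table)[0].q <= 0.01
        assert hits >= 95

    def test_temperature_shift_absorbed_by_covariate(self, rng):
        rejections = 0
        for _ in range(100):
            table = omnibus_table([0.4, 0.4, 0.4], rng=rng, temp_pp=20.0)
            rejections += time_omnibus(table)[0].q <= 0.01
        assert rejections <= 5

    def test_without_temperature_equals_three_group_pooled_test(self, rng):
        table = omnibus_table([0.2, 0.5, 0.7], rng=rng)
        rec = time_omnibus(table, include_temperature=False)[0]
        # closed form: group-pooled MLEs vs overall pooled proportion
        times = table.time_points()
        ll_alt = ll_null = 0.0
        m_all = table.methylated.sum()
        c_all = table.coverage.sum()
        p0 = m_all / c_all
        for t in (1, 2, 3):
            m = table.methylated[0, times == t].sum()
            c = table.coverage[0, times == t].sum()
            ll_alt += xlogy(m, m / c) + xlogy(c - m, 1 - m / c)
            ll_null += xlogy(m, p0) + xlogy(c - m, 1 - p0)
        assert rec.lrt_stat == pytest.approx(2 * (ll_alt - ll_null), abs=1e-5)

    def test_requires_all_three_time_points(self):
        table = make_table([[10, 10]], [[5, 5]], times=(1, 2))
        with pytest.raises(ValidationError):
            time_omnibus(table)


class TestTissueClassification:
    def _rec(self, pos, tissue, is_dms):
        from crossmeth.dms import DMSRecord

        return DMSRecord(
            site=GenomicSite("chr1", pos, "+"),
            tissue=tissue,
            contrast=D12,
            meth_diff=20.0,
            lrt_stat=5.0,
            df=1,
            p=0.01,
            q=0.01,
            is_dms=is_dms,
        )

    def test_classification_rules(self):
        rbc = [self._rec(100, "RBC", True), self._rec(200, "RBC", True), self._rec(300, "RBC", False)]
        liv = [self._rec(100, "liver", True), self._rec(200, "liver", False), self._rec(300, "liver", False)]
        out = classify_tissue_generality(rbc, liv, D12)
        klass = {r.site.pos: r.klass for r in out}
        assert klass == {100: "general", 200: "rbc_specific"}  # both-null site omitted

    def test_contrast_mismatch_rejected(self):
        rbc = [self._rec(100, "RBC", True)]
        liv = [self._rec(100, "liver", True)]
        with pytest.raises(ValidationError):
            classify_tissue_generality(rbc, liv, ContrastSpec.delta23())
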