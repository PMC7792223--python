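import numpy as np
import pytest
from scipy.stats import hypergeom

from crossmeth.dms import DMSRecord
from crossmeth.expression import DEGeneRecord
from crossmeth.integrate import (
    QuadrantAssociation,
    assign_quadrant,
    build_quadrant_associations,
    correlate_candidate_gene,
    fisher_enrichment,
    mean_methylation_change,
    pairwise_change_matrix,
)
from crossmeth.regions import RegionAssignment
from crossmeth.types import (
    ContrastSpec,
    GenomicSite,
    MethylationProportionMatrix,
    ValidationError,
)

from conftest import make_samples

D12 = ContrastSpec.delta12()


class TestPairwiseChange:
    def test_exhaustive_enumeration_example(self):
        vec = pairwise_change_matrix([1.0, 2.0], [3.0, 5.0], D12)
        # earlier females first: mean over later values minus own value
        np.testing.assert_allclose(vec.change, [3.0, 2.0, 1.5, 3.5])

    def test_identical_values_all_zero(self):
        vec = pairwise_change_matrix([2.0, 2.0], [2.0, 2.0], D12)
        np.testing.assert_allclose(vec.change, 0.0)

    def test_single_female_collapse(self):
        vec = pairwise_change_matrix([1.0], [4.0], D12)
        np.testing.assert_allclose(vec.change, [3.0, 3.0])

    def test_mean_equals_difference_of_time_means(self, rng):
        earlier = rng.normal(size=6)
        later = rng.normal(size=6)
        vec = pairwise_change_matrix(earlier, later, D12)
        assert vec.change.mean() == pytest.approx(later.mean() - earlier.mean())

    def test_swapping_roles_negates(self, rng):
        earlier = rng.normal(size=4)
        later = rng.normal(size=4)
        fwd = pairwise_change_matrix(earlier, later, D12)
        rev = pairwise_change_matrix(later, earlier, D12)
        # matched females appear in opposite halves with negated changes
        np.testing.assert_allclose(fwd.change[:4], -rev.change[4:])
        np.testing.assert_allclose(fwd.change[4:], -rev.change[:4])

    def test_missing_female_omitted_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            vec = pairwise_change_matrix([1.0, np.nan], [3.0], D12)
        assert len(vec.change) == 2


class TestCandidateCorrelation:
    def test_perfect_negative_relation(self):
        meth = pairwise_change_matrix([1.0, 2.0], [3.0, 5.0], D12)
        expr = pairwise_change_matrix([-1.0, -2.0], [-3.0, -5.0], D12)
        res = correlate_candidate_gene(meth, expr)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        meth = pairwise_change_matrix([3.0, 2.5], [1.5, 3.5], D12)
        expr = pairwise_change_matrix([1.0, 1.0], [1.0, 1.0], D12)
        res = correlate_candidate_gene(meth, expr)
        assert res.undefined

    def test_null_rejection_rate_matches_t_distribution(self, rng):
        # with 12 paired values, two-sided p <= 0.05 iff |r| >= 0.576
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) >= 0.576
        assert 0.03 <= hits / n_rep <= 0.07

    def test_small_n_rejected(self):
        meth = pairwise_change_matrix([1.0], [2.0], D12)
        with pytest.raises(ValidationError):
            correlate_candidate_gene(meth, meth)


class TestQuadrants:
    @pytest.mark.parametrize(
        "delta,lfc,quadrant",
        [(-10.0, 0.8, "Q1"), (6.0, 0.6, "Q2"), (10.0, -0.8, "Q3"), (-6.0, -0.6, "Q4")],
    )
    def test_sign_rules(self, delta, lfc, quadrant):
        assert assign_quadrant(delta, lfc) == quadrant

    def test_zero_input_is_contract_violation(self):
        with pytest.raises(ValidationError):
            assign_quadrant(0.0, 1.0)


def dms_rec(pos, is_dms=True):
    return DMSRecord(
        site=GenomicSite("chr1", pos, "+"),
        tissue="RBC",
        contrast=ContrastSpec.omnibus(),
        meth_diff=0.0,
        lrt_stat=10.0,
        df=2,
        p=0.001,
        q=0.005,
        is_dms=is_dms,
    )


def de_rec(gene, lfc12, passes=True):
    return DEGeneRecord(
        gene, "ovary", p_time=0.001, q_time=0.01, log2fc_12=lfc12, log2fc_23=0.0,
        passes_filter=passes,
    )


class TestAssociations:
    def _assignment(self, pos, pairs):
        return RegionAssignment({GenomicSite("chr1", pos, "+"): pairs})

    def test_association_built_and_trimmed(self):
        assignment = self._assignment(100, [("gA", "TSS")])
        delta = {GenomicSite("chr1", 100, "+"): 20.0}
        out = build_quadrant_associations(
            [dms_rec(100)], [de_rec("gA", -1.0)], assignment, delta, D12, "RBC-ovary"
        )
        assert len(out) == 1
        assert out[0].quadrant == "Q3"

    def test_small_methylation_change_excluded(self):
        assignment = self._assignment(100, [("gA", "TSS")])
        delta = {GenomicSite("chr1", 100, "+"): 4.9}
        out = build_quadrant_associations(
            [dms_rec(100)], [de_rec("gA", -1.0)], assignment, delta, D12, "RBC-ovary"
        )
        assert out == []

    def test_small_expression_change_excluded(self):
        assignment = self._assignment(100, [("gA", "TSS")])
        delta = {GenomicSite("chr1", 100, "+"): 20.0}
        out = build_quadrant_associations(
            [dms_rec(100)], [de_rec("gA", 0.4)], assignment, delta, D12, "RBC-ovary"
        )
        assert out == []

    def test_multi_region_site_counted_once_per_region(self):
        assignment = self._assignment(100, [("gA", "TSS"), ("gA", "promoter")])
        delta = {GenomicSite("chr1", 100, "+"): 20.0}
        out = build_quadrant_associations(
            [dms_rec(100)], [de_rec("gA", -1.0)], assignment, delta, D12, "RBC-ovary"
        )
        assert sorted(a.region for a in out) == ["TSS", "promoter"]

    def test_empty_inputs_warn(self, caplog):
        with caplog.at_level("WARNING"):
            out = build_quadrant_associations(
                [], [], RegionAssignment({}), {}, D12, "RBC-ovary"
            )
        assert out == []


def test_mean_methylation_change_is_percentage_difference():
    samples = make_samples(n_per_time=2)
    values = np.array([[0.10, 0.20, 0.40, 0.50, 0.0, 0.0]])
    sites = [GenomicSite("chr1", 100, "+")]
    props = MethylationProportionMatrix(sites, samples, values)
    delta = mean_methylation_change(props, D12)
    assert delta[sites[0]] == pytest.approx(30.0)


def assoc(region, quadrant, i):
    delta = -10.0 if quadrant in ("Q1", "Q4") else 10.0
    lfc = 1.0 if quadrant in ("Q1", "Q2") else -1.0
    return QuadrantAssociation(
        GenomicSite("chr1", i, "+"), f"g{i}", region, "RBC-ovary", "d12", delta, lfc, quadrant
    )


def table_to_assocs(table):
    out, i = [], 0
    for region, (n13, n24) in zip(("TSS", "down10kb"), table):
        for _ in range(n13):
            i += 1
            out.append(assoc(region, "Q1", i))
        for _ in range(n24):
            i += 1
            out.append(assoc(region, "Q2", i))
    return out


def fisher_oracle(table):
    """Exhaustive two-sided Fisher p: sum hypergeometric probabilities not
    larger than the observed table's (with the standard relative slack)."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    support = range(max(0, k - n2), min(k, n1) + 1)
    pmf = {x: hypergeom.pmf(x, n1 + n2, n1, k) for x in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisherEnrichment:
    def test_balanced_table_no_association(self):
        res = fisher_enrichment(table_to_assocs([[5, 5], [5, 5]]))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_enumerated_example_8_2_2_8(self):
        res = fisher_enrichment(table_to_assocs([[8, 2], [2, 8]]))
        assert res.p == pytest.approx(4252 / 184756, abs=1e-6)

    def test_enumerated_example_with_zero_cells(self):
        res = fisher_enrichment(table_to_assocs([[3, 0], [0, 3]]))
        assert res.p == pytest.approx(0.1, abs=1e-9)
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((3.5 * 3.5) / (0.5 * 0.5))

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(0, 11, size=(2, 2))
            if table[0].sum() == 0 or table[1].sum() == 0:
                continue
            res = fisher_enrichment(table_to_assocs(table.tolist()))
            assert res.p == pytest.approx(fisher_oracle(table), abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError, match="down10kb"):
            fisher_enrichment(table_to_assocs([[3, 3], [0, 0]]))
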