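import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from crossmeth.regions import build_region_intervals
from crossmeth.simulate import (
    SimulationConfig,
    simulate_associations,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
)
from crossmeth.types import ValidationError


def small_config(seed=7, **kw):
    kw.setdefault("n_sites", 800)
    kw.setdefault("n_genes", 15)
    kw.setdefault("chrom_length", 2_000_000)
    return SimulationConfig(seed=seed, **kw)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        outputs = []
        for _ in range(2):
            cfg = small_config()
            genes, sites = simulate_genome(cfg)
            tables, truth = simulate_methylation(cfg, sites)
            expr, cand = simulate_expression(cfg, genes, sites, truth)
            outputs.append((genes, sites, tables, truth, expr, cand))
        (g1, s1, t1, tr1, e1, c1), (g2, s2, t2, tr2, e2, c2) = outputs
        assert [g.gene_id for g in g1] == [g.gene_id for g in g2]
        assert s1 == s2
        for tissue in t1:
            np.testing.assert_array_equal(t1[tissue].coverage, t2[tissue].coverage)
            np.testing.assert_array_equal(t1[tissue].methylated, t2[tissue].methylated)
        assert tr1.site_truth.equals(tr2.site_truth)
        for tissue in e1:
            np.testing.assert_array_equal(e1[tissue].counts, e2[tissue].counts)
        assert c1.equals(c2)

    def test_different_seeds_differ(self):
        t1, _ = simulate_methylation(small_config(seed=1), simulate_genome(small_config(seed=1))[1])
        t2, _ = simulate_methylation(small_config(seed=2), simulate_genome(small_config(seed=2))[1])
        assert not np.array_equal(t1["RBC"].methylated, t2["RBC"].methylated)


class TestGenome:
    def test_every_gene_has_a_tss_site(self):
        cfg = small_config()
        genes, sites = simulate_genome(cfg)
        tss = [iv for iv in build_region_intervals(genes) if iv.region == "TSS"]
        positions = np.array([s.pos for s in sites])
        for iv in tss:
            assert ((positions >= iv.start) & (positions <= iv.end)).any()

    def test_genes_do_not_overlap(self):
        genes, _ = simulate_genome(small_config())
        spans = sorted((g.tx_start, g.tx_end) for g in genes)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValidationError, match="chrom_length"):
            simulate_genome(SimulationConfig(seed=1, n_genes=100, chrom_length=100_000))


class TestMethylationModel:
    def test_cohort_design(self):
        tables, _ = simulate_methylation(small_config(), simulate_genome(small_config())[1])
        for tissue, table in tables.items():
            assert table.n_samples == 18
            times = table.time_points()
            assert [int((times == t).sum()) for t in (1, 2, 3)] == [6, 6, 6]
            warm = sum(s.temperature_env == "warm" for s in table.samples)
            assert warm == 9

    def test_marginal_mean_tracks_baseline(self):
        cfg = small_config(n_sites=5000, baseline_logit_mean=0.0, fraction_temporal=0.0)
        _, sites = simulate_genome(cfg)
        tables, _ = simulate_methylation(cfg, sites)
        props = tables["RBC"].proportions()
        mean = np.nanmean(props.values)
        assert mean == pytest.approx(expit(0.0), abs=0.02)

    def test_rho_zero_counts_are_binomial(self):
        # Pearson dispersion statistic over cells against per-site pooled
        # proportions should sit inside the 95% chi-square band
        cfg = small_config(
            n_sites=250,
            rho=0.0,
            fraction_temporal=0.0,
            sample_shift_sd=0.0,
            family_sd=0.0,
        )
        _, sites = simulate_genome(cfg)
        tables, _ = simulate_methylation(cfg, sites)
        table = tables["RBC"]
        cov = table.coverage.astype(float)
        meth = table.methylated.astype(float)
        p_hat = meth.sum(axis=1) / cov.sum(axis=1)
        keep = (p_hat > 0.05) & (p_hat < 0.95)
        mu = cov * p_hat[:, None]
        var = cov * (p_hat * (1 - p_hat))[:, None]
        x2 = ((meth[keep] - mu[keep]) ** 2 / var[keep]).sum()
        df = keep.sum() * (table.n_samples - 1)
        lo, hi = stats.chi2.ppf([0.025, 0.975], df)
        assert lo < x2 < hi

    def test_tissue_specific_effects_only_in_assigned_tissue(self):
        cfg = small_config(fraction_general=0.0, fraction_temporal=0.3)
        _, sites = simulate_genome(cfg)
        _, truth = simulate_methylation(cfg, sites)
        st = truth.site_truth
        temporal = st[st["is_temporal"]]
        assert set(temporal["affected_tissue"]) <= {"RBC", "liver"}
        assert not temporal["is_general"].any()


class TestExpressionModel:
    def test_uncoupled_expression_independent_of_methylation(self):
        cfg = small_config(coupling_k=0.0, fraction_temporal=0.3)
        genes, sites = simulate_genome(cfg)
        _, truth = simulate_methylation(cfg, sites)
        simulate_expression(cfg, genes, sites, truth)
        gt = truth.gene_truth
        assert not gt["is_coupled"].any()

    def test_coupling_rule_exact_without_noise(self):
        cfg = small_config(
            coupling_k=0.05,
            coupling_noise_sd=0.0,
            fraction_temporal=0.6,
            coupling_target_tissue="ovary",
        )
        genes, sites = simulate_genome(cfg)
        _, truth = simulate_methylation(cfg, sites)
        simulate_expression(cfg, genes, sites, truth)
        gt = truth.gene_truth
        coupled = gt[(gt["tissue"] == "ovary") & gt["is_coupled"]]
        assert len(coupled) > 0
        st = truth.site_truth
        tss = {
            iv.gene_id: iv for iv in build_region_intervals(genes) if iv.region == "TSS"
        }
        for _, row in coupled.iterrows():
            iv = tss[row["gene_id"]]
            in_tss = st[
                st["is_temporal"]
                & st["affected_tissue"].isin(["both", "RBC"])
                & (st["pos"] >= iv.start)
                & (st["pos"] <= iv.end)
            ]
            expected = -0.05 * in_tss["true_d12_pp"].mean()
            assert row["shift12_log2"] == pytest.approx(expected, abs=1e-9)

    def test_pool_layout(self):
        cfg = small_config()
        genes, sites = simulate_genome(cfg)
        _, truth = simulate_methylation(cfg, sites)
        expr, _ = simulate_expression(cfg, genes, sites, truth)
        for tissue, mat in expr.items():
            assert len(mat.pools) == 6  # 2 pools x 3 time points
            assert all(p.pool_id for p in mat.pools)


def test_association_generator_respects_trimming(rng):
    assocs = simulate_associations(rng, n_per_region=25, k=0.05)
    assert len(assocs) == 50
    for a in assocs:
        assert abs(a.delta_meth) >= 5.0
        assert abs(a.log2fc) >= 0.5
        assert a.region in ("TSS", "down10kb")
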