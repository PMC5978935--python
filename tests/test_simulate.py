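import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ddrmeth import (SimConfig, simulate_annotation, simulate_expression,
                     simulate_methylation, simulate_study, simulate_survival)


class TestAnnotation:
    def test_one_cpg_per_gene(self):
        cfg = SimConfig(n_genes=10, cpgs_per_gene=(1, 1), seed=1)
        ann = simulate_annotation(cfg)
        assert (ann["region_class"] == "promoter").sum() == 10

    def test_intergenic_probes_far_from_every_tss(self, small_study):
        ann = small_study["ann"]
        prom = ann[ann["region_class"] == "promoter"]
        tss = (prom["pos"] - prom["tss_distance"]).groupby(prom["gene"]).first()
        tss_chrom = prom.groupby("gene")["chrom"].first()
        inter = ann[ann["region_class"] == "intergenic"]
        for chrom, sub in inter.groupby("chrom"):
            gene_tss = tss[tss_chrom == chrom].to_numpy()
            if len(gene_tss) == 0:
                continue
            dmin = np.abs(sub["pos"].to_numpy()[:, None] - gene_tss[None, :]).min(axis=1)
            assert (dmin > 1500).all()

    def test_region_classes_partition_probes(self, small_study):
        ann = small_study["ann"]
        counts = ann["region_class"].value_counts()
        assert counts.sum() == len(ann)
        assert set(counts.index) <= {"promoter", "intergenic", "other"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(subtype_proportions={"IDHwt": 0.5, "IDHmt-noncodel": 0.2,
                                           "IDHmt-codel": 0.2}).validate()
        with pytest.raises(ValueError):
            SimConfig(state_means_M=(0.0, 0.0, 4.0)).validate()


class TestMethylation:
    def test_mixture_identity(self, small_study):
        ms, truth = small_study["ms"], small_study["truth"]
        w = truth.purity.to_numpy()[:, None]
        recon = w * truth.beta_tumor.to_numpy() + (1 - w) * truth.beta_normal.to_numpy()
        assert np.abs(recon - ms.beta.to_numpy()).max() <= 1e-12

    def test_ntb_equals_normal_component_bitwise(self, small_study):
        ms, truth = small_study["ms"], small_study["truth"]
        ntb = ms.samples.index[ms.samples["tissue_type"] == "NTB"]
        assert (ms.beta.loc[ntb].to_numpy()
                == truth.beta_normal.loc[ntb].to_numpy()).all()

    def test_betas_open_interval_and_intensities_positive(self, small_study):
        beta = small_study["ms"].beta.to_numpy()
        assert beta.min() > 0 and beta.max() < 1
        its = small_study["its"]
        assert its.meth.to_numpy().min() > 0 and its.unmeth.to_numpy().min() > 0

    def test_intensity_beta_identity(self, small_study):
        ms, its = small_study["ms"], small_study["its"]
        assert np.abs(its.beta().to_numpy() - ms.beta.to_numpy()).max() <= 1e-10

    def test_null_shifts_leave_subtypes_equal(self):
        cfg = SimConfig(n_datasets=1, n_samples_per_dataset=60, n_genes=80,
                        cimp_shift_M=0.0, codel_extra_shift_M=0.0, seed=5)
        ann = simulate_annotation(cfg)
        ms, _, truth = simulate_methylation(cfg, ann)
        prom = ann.index[ann["region_class"] == "promoter"]
        samp = ms.samples
        tumor = samp["tissue_type"] == "tumor"
        m_mean = ms.M.loc[tumor, prom].mean(axis=1)
        codel = samp.loc[tumor, "codel"]
        res = stats.ttest_ind(m_mean[codel], m_mean[~codel])
        assert res.pvalue > 0.01

    def test_codel_reduces_arm_intensity(self, small_study):
        ms, its, ann = small_study["ms"], small_study["its"], small_study["ann"]
        truth = small_study["truth"]
        arm = ann.index[ann["chrom"].isin(["1p", "19q"])]
        ratio = np.log2(its.total[arm]).mean(axis=1) - np.log2(
            its.total.drop(columns=arm)
        ).mean(axis=1)
        tumor = ms.samples["tissue_type"] == "tumor"
        codel = truth.codel[tumor]
        assert ratio[tumor][codel].mean() < ratio[tumor][~codel].mean()

    def test_byte_identical_determinism(self, small_cfg):
        ann1 = simulate_annotation(small_cfg)
        ms1, its1, t1 = simulate_methylation(small_cfg, ann1)
        ann2 = simulate_annotation(small_cfg)
        ms2, its2, t2 = simulate_methylation(small_cfg, ann2)
        assert ann1.equals(ann2)
        assert (ms1.beta.to_numpy() == ms2.beta.to_numpy()).all()
        assert (its1.meth.to_numpy() == its2.meth.to_numpy()).all()
        assert (t1.purity.to_numpy() == t2.purity.to_numpy()).all()

    def test_different_seed_changes_output(self, small_cfg):
        cfg2 = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        ms1 = simulate_methylation(small_cfg, simulate_annotation(small_cfg))[0]
        ms2 = simulate_methylation(cfg2, simulate_annotation(cfg2))[0]
        assert not ms1.beta.equals(ms2.beta)


class TestExpression:
    def test_noiseless_coupling_gives_perfect_negative_correlation(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, expression_noise_sd=0.0,
                                  coupling_slope=-1.0)
        ann = simulate_annotation(cfg)
        ms, _, truth = simulate_methylation(cfg, ann)
        expr = simulate_expression(cfg, ms, ann, truth)
        from ddrmeth.simulate import mean_promoter_m

        meanM = mean_promoter_m(ms, ann, truth.functional_genes)
        for gene in truth.functional_genes:
            r = np.corrcoef(meanM[gene], expr[gene])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-10)

    def test_nonfunctional_genes_uncoupled(self, small_cfg, small_study):
        ann, ms, truth = (small_study["ann"], small_study["ms"],
                          small_study["truth"])
        expr = simulate_expression(small_cfg, ms, ann, truth)
        from ddrmeth.simulate import mean_promoter_m

        other = [g for g in expr.columns if g not in truth.functional_genes][:10]
        meanM = mean_promoter_m(ms, ann, other)
        rs = [abs(np.corrcoef(meanM[g], expr[g])[0, 1]) for g in other
              if g in meanM.columns]
        assert np.mean(rs) < 0.3


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = SimConfig(censor_rate=0.0, seed=2)
        scores = pd.Series(np.zeros(50), index=[f"s{i}" for i in range(50)])
        tab, _ = simulate_survival(cfg, scores)
        assert (tab["event"] == 1).all()

    def test_arms_one_to_one(self):
        cfg = SimConfig(seed=3)
        scores = pd.Series(np.zeros(100), index=[f"s{i}" for i in range(100)])
        tab, _ = simulate_survival(cfg, scores)
        assert (tab["arm"] == "TMZ").sum() == 50

    def test_null_hazard_pvalues_uniform(self):
        from lifelines.statistics import logrank_test

        cfg = SimConfig(seed=4)
        cfg.hazard_params.treat_coef = 0.0
        cfg.hazard_params.score_coef = 0.0
        cfg.hazard_params.interaction_coef = 0.0
        ps = []
        for rep in range(40):
            rng = np.random.default_rng(500 + rep)
            scores = pd.Series(rng.normal(0, 1, 80),
                               index=[f"s{i}" for i in range(80)])
            tab, _ = simulate_survival(cfg, scores, rng=rng)
            a, b = tab[tab["arm"] == "RT"], tab[tab["arm"] == "TMZ"]
            ps.append(logrank_test(a["time"], b["time"], a["event"],
                                   b["event"]).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rejects_nonfinite_scores(self):
        cfg = SimConfig(seed=5)
        with pytest.raises(ValueError):
            simulate_survival(cfg, pd.Series([0.0, np.inf]))


def test_study_bundle_coherent(small_cfg):
    bundle = simulate_study(small_cfg)
    assert bundle.expression.index.equals(bundle.methylation.samples.index)
    assert set(bundle.survival.index) <= set(bundle.methylation.samples.index)
    assert bundle.mgmt_gene in bundle.truth.functional_genes
    assert bundle.truth.survival_linpred is not None
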